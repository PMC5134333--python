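"""Reading screening CSVs, writing chains/summaries, and block prediction.

Input format, one observation per line (header optional):

    compound name, channel name, experiment number, dose (uM), response (% inhibition)

Raw responses outside [0, 100] are capped into the interval with a logged
warning, matching how screening platforms cap % block at source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import hill_response
from .dataset import DoseResponseDataset
from .hierarchical import posterior_predictive
from .mcmc import PosteriorChain

__all__ = [
    "read_csv",
    "write_chain",
    "read_chain",
    "write_fit_outputs",
    "BlockPredictionSamples",
    "predict_block",
    "predict_from_chain",
    "COLUMNS",
]

logger = logging.getLogger("hillbayes")

COLUMNS = ["compound", "channel", "experiment", "dose", "response"]


def _has_header(path: Path) -> bool:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    fields = [f.strip() for f in first.split(",")]
    if len(fields) < 5:
        return False  # let the column-count check report this row
    try:
        float(fields[3]), float(fields[4])
    except ValueError:
        return True
    return False


def read_csv(
    path, compound: str | None = None, channel: str | None = None
) -> DoseResponseDataset:
    """Load dose-response records, optionally filtering by compound/channel.

    Raises ``ValueError`` naming the offending line for malformed rows, and
    if no records survive the filters.
    """
    path = Path(path)
    header = 0 if _has_header(path) else None
    offset = 2 if header == 0 else 1  # 1-based line number of the first record
    try:
        raw = pd.read_csv(path, header=header, skipinitialspace=True,
                          float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    if raw.shape[1] != 5:
        missing = COLUMNS[raw.shape[1] :]
        raise ValueError(
            f"{path}: expected 5 columns "
            f"(compound, channel, experiment, dose, response); "
            f"got {raw.shape[1]} — missing {', '.join(missing)}"
        )
    df = raw.set_axis(COLUMNS, axis=1)

    for col in ("experiment", "dose", "response"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + offset
            raise ValueError(
                f"{path}:{line}: field '{col}' is not numeric: {df[col][bad.idxmax()]!r}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + offset
            raise ValueError(f"{path}:{line}: field '{col}' is empty")
        df[col] = converted

    if compound is not None:
        df = df[df["compound"].astype(str).str.strip() == compound]
    if channel is not None:
        df = df[df["channel"].astype(str).str.strip() == channel]
    if df.empty:
        raise ValueError(
            f"{path}: no records left after filtering "
            f"(compound={compound!r}, channel={channel!r})"
        )

    responses = df["response"].to_numpy(dtype=float)
    n_low = int((responses < 0).sum())
    n_high = int((responses > 100).sum())
    if n_low or n_high:
        logger.warning(
            "%s: capped %d response(s) below 0%% and %d above 100%% into [0, 100]",
            path, n_low, n_high,
        )
        responses = np.clip(responses, 0.0, 100.0)

    compounds = df["compound"].astype(str).str.strip().unique()
    channels = df["channel"].astype(str).str.strip().unique()
    return DoseResponseDataset(
        df["dose"].to_numpy(dtype=float),
        responses,
        df["experiment"].to_numpy(dtype=int),
        compound=compounds[0] if len(compounds) == 1 else "mixed",
        channel=channels[0] if len(channels) == 1 else "mixed",
    )


def write_dataset(data: DoseResponseDataset, path) -> None:
    """Write records in the standard 5-column CSV layout (with header)."""
    data.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_chain(chain: PosteriorChain, path) -> None:
    """Posterior samples as CSV, one named column per parameter plus
    log_posterior, at full double precision (lossless round trip)."""
    if len(chain) == 0:
        raise ValueError("refusing to write an empty chain")
    chain.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_chain(path) -> pd.DataFrame:
    """Read a chain CSV written by :func:`write_chain`.

    Uses correctly-rounded float parsing so the write/read cycle is
    bit-lossless.
    """
    return pd.read_csv(path, float_precision="round_trip")


def write_fit_outputs(chain: PosteriorChain, out_dir) -> Path:
    """Write chain.csv, summary.csv and metadata.txt into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_chain(chain, out / "chain.csv")
    chain.summary().to_csv(out / "summary.csv", index=False, float_format="%.10g")
    with open(out / "metadata.txt", "w", encoding="utf-8") as fh:
        for key, val in chain.meta.items():
            fh.write(f"{key}: {val}\n")
        fh.write(f"n_retained_samples: {len(chain)}\n")
        fh.write(f"acceptance_rate: {chain.acceptance_rate:.4f}\n")
    return out


@dataclass(frozen=True)
class BlockPredictionSamples:
    """Distribution of % block at one concentration, as posterior samples."""

    concentration: float
    block_samples: np.ndarray
    source: str  # 'single-level' | 'hierarchical-underlying' | 'hierarchical-predictive'


def predict_block(
    pic50_samples, hill_samples, concentration: float, source: str = "single-level"
) -> BlockPredictionSamples:
    """% block at ``concentration`` for each (pIC50, Hill) posterior sample."""
    pic50_samples = np.atleast_1d(np.asarray(pic50_samples, dtype=float))
    hill_samples = np.atleast_1d(np.asarray(hill_samples, dtype=float))
    if pic50_samples.size == 0 or pic50_samples.shape != hill_samples.shape:
        raise ValueError("need matching, non-empty pIC50 and Hill sample arrays")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    block = hill_response(concentration, pic50_samples, hill_samples)
    return BlockPredictionSamples(float(concentration), np.atleast_1d(block), source)


def predict_from_chain(
    chain_df: pd.DataFrame,
    concentration: float,
    mode: str = "single",
    seed: int | np.random.Generator = 0,
) -> BlockPredictionSamples:
    """Block prediction from a stored chain.

    ``mode='single'`` uses the (pIC50, Hill) columns of a single-level
    chain; ``'underlying'`` uses the hierarchical (mu, alpha) columns as
    typical pIC50/Hill values; ``'predictive'`` draws one future-experiment
    (pIC50, Hill) pair per retained iteration from the posterior-predictive
    mixtures before evaluating the curve.
    """
    if mode == "single":
        return predict_block(
            chain_df["pIC50"].to_numpy(), chain_df["Hill"].to_numpy(),
            concentration, "single-level",
        )
    if mode == "underlying":
        return predict_block(
            chain_df["mu"].to_numpy(), chain_df["alpha"].to_numpy(),
            concentration, "hierarchical-underlying",
        )
    if mode == "predictive":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = len(chain_df)
        pic50_dist = posterior_predictive(
            chain_df["mu"].to_numpy(), chain_df["s"].to_numpy(), "pIC50"
        )
        hill_dist = posterior_predictive(
            chain_df["alpha"].to_numpy(), chain_df["beta"].to_numpy(), "Hill"
        )
        pred = predict_block(
            pic50_dist.sample(n, rng), hill_dist.sample(n, rng),
            concentration, "hierarchical-predictive",
        )
        return pred
    raise ValueError("mode must be 'single', 'underlying' or 'predictive'")
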