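"""Container for dose-response records grouped by experimental repeat."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DoseResponseDataset"]


@dataclass(frozen=True)
class DoseResponseDataset:
    """Dose-response observations for one compound/channel combination.

    Parameters
    ----------
    doses : array of float
        Applied compound concentrations, micromolar, one per record.
    responses : array of float
        Observed % channel block, in [0, 100] (ingest is responsible for
        capping raw values outside this range).
    experiment_ids : array of int
        1-based experiment (repeat) label per record.  Records sharing a
        label came from the same cell/experiment and share per-experiment
        parameters in the hierarchical model.
    compound, channel : str
        Labels carried through to output files.
    """

    doses: np.ndarray
    responses: np.ndarray
    experiment_ids: np.ndarray
    compound: str = "compound"
    channel: str = "channel"

    def __post_init__(self) -> None:
        doses = np.atleast_1d(np.asarray(self.doses, dtype=float))
        responses = np.atleast_1d(np.asarray(self.responses, dtype=float))
        exp_ids = np.atleast_1d(np.asarray(self.experiment_ids, dtype=int))
        if not (doses.shape == responses.shape == exp_ids.shape):
            raise ValueError("doses, responses and experiment_ids must have equal length")
        if doses.size == 0:
            raise ValueError("dataset must contain at least one record")
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any((responses < 0) | (responses > 100)):
            raise ValueError("responses must lie in [0, 100]; cap raw data on ingest")
        if np.any(exp_ids < 1):
            raise ValueError("experiment ids must be positive integers")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "responses", responses)
        object.__setattr__(self, "experiment_ids", exp_ids)

    @property
    def n_records(self) -> int:
        """Total number of data points K."""
        return int(self.doses.size)

    @property
    def n_experiments(self) -> int:
        """Number of distinct experiments Ne."""
        return int(np.unique(self.experiment_ids).size)

    @property
    def experiment_labels(self) -> np.ndarray:
        """Sorted distinct experiment labels."""
        return np.unique(self.experiment_ids)

    def records_per_experiment(self) -> dict[int, int]:
        labels, counts = np.unique(self.experiment_ids, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def experiment(self, label: int) -> "DoseResponseDataset":
        """Sub-dataset for one experiment label."""
        mask = self.experiment_ids == label
        if not mask.any():
            raise KeyError(f"no records for experiment {label}")
        return DoseResponseDataset(
            self.doses[mask], self.responses[mask], self.experiment_ids[mask],
            self.compound, self.channel,
        )

    def by_experiment(self):
        """Iterate ``(label, doses, responses)`` in sorted label order."""
        for label in self.experiment_labels:
            mask = self.experiment_ids == label
            yield int(label), self.doses[mask], self.responses[mask]

    def to_frame(self) -> pd.DataFrame:
        """Records in the standard 5-column CSV layout."""
        return pd.DataFrame(
            {
                "compound": self.compound,
                "channel": self.channel,
                "experiment": self.experiment_ids,
                "dose": self.doses,
                "response": self.responses,
            }
        )
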