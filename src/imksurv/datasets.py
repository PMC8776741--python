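"""Clonogenic survival observations as a tidy, replicate-aware table."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("cell_line", "protocol_id", "dose_Gy", "neg_log_S", "replicate")


@dataclass(frozen=True)
class SurvivalDataset:
    """Observed (cell line, protocol, dose, -ln S, replicate) records.

    The response is stored on the -ln S scale, matching the Gaussian error
    model used by the likelihood.  ``meta`` carries provenance (generator
    truth parameters, seeds) for synthetic data.
    """

    records: pd.DataFrame
    meta: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        if np.any(df["dose_Gy"].to_numpy() < 0):
            raise ValueError("doses must be non-negative")
        if not np.all(np.isfinite(df["neg_log_S"].to_numpy())):
            raise ValueError("neg_log_S values must be finite")
        object.__setattr__(
            self, "records", df.reset_index(drop=True)[list(REQUIRED_COLUMNS)]
        )

    @classmethod
    def from_observations(
        cls,
        cell_line: str,
        doses,
        neg_log_S,
        replicate=None,
        protocol_id: str = "acute",
        meta: Mapping[str, Any] | None = None,
    ) -> "SurvivalDataset":
        doses = np.asarray(doses, dtype=float)
        neg_log_S = np.asarray(neg_log_S, dtype=float)
        if replicate is None:
            replicate = np.zeros(len(doses), dtype=int)
        df = pd.DataFrame(
            {
                "cell_line": cell_line,
                "protocol_id": protocol_id,
                "dose_Gy": doses,
                "neg_log_S": neg_log_S,
                "replicate": np.asarray(replicate),
            }
        )
        return cls(df, meta=dict(meta or {}))

    @property
    def N(self) -> int:
        return len(self.records)

    @property
    def cell_lines(self) -> list[str]:
        return list(dict.fromkeys(self.records["cell_line"]))

    def pooled_replicate_sd(self) -> float:
        """Pooled SD of -ln S across replicates within (protocol, dose) cells.

        Default residual scale sigma for the likelihood when not set
        explicitly; requires at least one cell with >= 2 replicates.
        Zero-dose cells are excluded: survival there is capped at 1 by the
        plating-efficiency normalization, so their replicate spread is
        truncated and would bias the scale downward.
        """
        nonzero = self.records[self.records["dose_Gy"] > 0]
        grouped = nonzero.groupby(["cell_line", "protocol_id", "dose_Gy"])[
            "neg_log_S"
        ]
        ss, dof = 0.0, 0
        for _, vals in grouped:
            if len(vals) >= 2:
                ss += float(np.sum((vals - vals.mean()) ** 2))
                dof += len(vals) - 1
        if dof == 0:
            raise ValueError(
                "cannot pool replicate variance: no (protocol, dose) cell has "
                ">= 2 replicates; set sigma explicitly"
            )
        return float(np.sqrt(ss / dof))

    def subset(self, cell_line: str) -> "SurvivalDataset":
        df = self.records[self.records["cell_line"] == cell_line]
        if df.empty:
            raise KeyError(f"no records for cell line {cell_line!r}")
        return SurvivalDataset(df, meta=self.meta)
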