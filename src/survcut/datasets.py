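"""Container for right-censored survival data with one biomarker and covariates.

The on-disk interchange format is a delimited text table with a header row and
columns ``time,event,<biomarker>,<covariates...>``; ``event`` is 0 (censored)
or 1 (event observed).  Every estimator in the package accepts the same
schema back.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset"]


@dataclass(frozen=True)
class SurvivalDataset:
    """One right-censored survival dataset.

    Parameters
    ----------
    data
        Table with one row per subject.  Must contain ``time_col``,
        ``event_col``, ``biomarker_col`` and every column in
        ``covariate_cols``; other columns are carried along untouched.
    time_col, event_col, biomarker_col, covariate_cols
        Column names.  Defaults match the simulator output
        (``time, event, X, Z1, Z2, Z3``).
    """

    data: pd.DataFrame
    time_col: str = "time"
    event_col: str = "event"
    biomarker_col: str = "X"
    covariate_cols: tuple[str, ...] = ("Z1", "Z2", "Z3")

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariate_cols", tuple(self.covariate_cols))
        cols = [self.time_col, self.event_col, self.biomarker_col, *self.covariate_cols]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        sub = self.data[cols]
        if sub.isna().any().any():
            raise ValueError("dataset contains missing values")
        t = self.time
        if not np.all(t > 0):
            raise ValueError("all follow-up times must be strictly positive")
        ev = np.asarray(self.data[self.event_col])
        if not np.isin(ev, (0, 1)).all():
            raise ValueError("event indicator must be 0 or 1")
        if ev.sum() < 1:
            raise ValueError("dataset must contain at least one event")
        if len(self.data) < 2:
            raise ValueError("dataset must contain at least two subjects")

    # -- array views -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data[self.time_col].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data[self.event_col].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def biomarker(self) -> np.ndarray:
        return self.data[self.biomarker_col].to_numpy(dtype=float)

    def covariates(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Covariate matrix (n, p) for ``names`` (default: ``covariate_cols``)."""
        names = list(names) if names is not None else list(self.covariate_cols)
        return self.data[names].to_numpy(dtype=float)

    # -- subsetting --------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        """Row subset by boolean mask or integer index array."""
        return replace(self, data=self.data.iloc[np.asarray(mask)].reset_index(drop=True))

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        time_col: str = "time",
        event_col: str = "event",
        biomarker_col: str = "X",
        covariate_cols: Sequence[str] | None = None,
    ) -> "SurvivalDataset":
        df = pd.read_csv(path)
        if covariate_cols is None:
            covariate_cols = [
                c for c in df.columns if c not in (time_col, event_col, biomarker_col)
            ]
        return cls(df, time_col, event_col, biomarker_col, tuple(covariate_cols))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)
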