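"""Panel containers and delimited-text I/O for areal count data.

:class:`PanelData` holds observed counts ``y_it``, expected counts ``e_it``
and optional covariates ``X_it`` on a complete region x time grid.  Files
are plain CSV with header columns ``region_id, time, count, expected`` plus
any number of covariate columns; readers validate and reject rather than
repair malformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PanelData", "read_panel", "write_panel"]

_REQUIRED = ["region_id", "time", "count", "expected"]


@dataclass
class PanelData:
    """Counts and expected counts on a region x time grid.

    ``y`` and ``e`` are ``(n_regions, n_times)`` arrays ordered by
    ``region_ids`` / ``times``; ``X`` is ``(n_regions, n_times, p)`` or None.
    """

    region_ids: list
    times: list
    y: np.ndarray
    e: np.ndarray
    X: np.ndarray | None = None
    covariate_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n, T = len(self.region_ids), len(self.times)
        self.y = np.asarray(self.y)
        self.e = np.asarray(self.e, dtype=float)
        if self.y.shape != (n, T) or self.e.shape != (n, T):
            raise ValueError(
                f"y and e must have shape ({n}, {T}); got {self.y.shape}, {self.e.shape}"
            )
        if np.any(self.y < 0) or not np.allclose(self.y, np.round(self.y)):
            raise ValueError("counts must be nonnegative integers")
        self.y = self.y.astype(np.int64)
        if np.any(~np.isfinite(self.e)) or np.any(self.e <= 0):
            raise ValueError("expected counts must be strictly positive and finite")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.ndim != 3 or self.X.shape[:2] != (n, T):
                raise ValueError("X must have shape (n_regions, n_times, p)")
            if len(self.covariate_names) != self.X.shape[2]:
                raise ValueError("covariate_names must match X's last dimension")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def sir(self) -> np.ndarray:
        """Crude standardized incidence ratio ``y/e``."""
        return self.y / self.e

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PanelData":
        missing = [c for c in _REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        dup = df.duplicated(subset=["region_id", "time"])
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValueError(f"duplicate (region_id, time) keys at rows {rows}")
        bad = df.index[df["expected"] <= 0].tolist()
        if bad:
            raise ValueError(f"nonpositive expected count at rows {bad}")
        bad = df.index[df["count"] < 0].tolist()
        if bad:
            raise ValueError(f"negative count at rows {bad}")
        regions = sorted(df["region_id"].astype(str).unique())
        times = sorted(df["time"].unique())
        wide_y = df.pivot(index="region_id", columns="time", values="count")
        if wide_y.isna().any().any():
            holes = [
                (str(i), t)
                for (i, t), v in wide_y.stack(future_stack=True).items()
                if pd.isna(v)
            ]
            raise ValueError(f"incomplete region x time grid; missing cells: {holes}")
        wide_y.index = wide_y.index.astype(str)
        wide_e = df.pivot(index="region_id", columns="time", values="expected")
        wide_e.index = wide_e.index.astype(str)
        cov = [c for c in df.columns if c not in _REQUIRED]
        X = None
        if cov:
            mats = []
            for c in cov:
                w = df.pivot(index="region_id", columns="time", values=c)
                w.index = w.index.astype(str)
                mats.append(w.loc[regions, times].to_numpy(dtype=float))
            X = np.stack(mats, axis=-1)
        return cls(
            region_ids=regions,
            times=list(times),
            y=wide_y.loc[regions, times].to_numpy(),
            e=wide_e.loc[regions, times].to_numpy(),
            X=X,
            covariate_names=cov,
        )

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for i, r in enumerate(self.region_ids):
            for t, tt in enumerate(self.times):
                rec = {
                    "region_id": r,
                    "time": tt,
                    "count": int(self.y[i, t]),
                    "expected": float(self.e[i, t]),
                }
                for k, c in enumerate(self.covariate_names):
                    rec[c] = float(self.X[i, t, k])
                recs.append(rec)
        return pd.DataFrame.from_records(recs)


def read_panel(path) -> PanelData:
    """Read and validate a panel CSV (columns region_id, time, count, expected)."""
    return PanelData.from_dataframe(pd.read_csv(path))


def write_panel(data: PanelData, path) -> None:
    data.to_dataframe().to_csv(path, index=False)
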