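"""Collective-variable trajectory container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CVTrajectory:
    """A time series of collective-variable values at a fixed frame interval.

    Parameters
    ----------
    data : (n_frames, n_cvs) float array
        One row per saved frame, one column per collective variable.
    frame_interval : float
        Physical time between consecutive frames (arbitrary but consistent
        time units; all reported passage times inherit them).
    columns : tuple of str, optional
        CV names; defaults to ``cv1..cvK``.
    """

    data: np.ndarray
    frame_interval: float = 1.0
    columns: tuple = field(default=None)

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ValueError("trajectory data must be a nonempty (n_frames, n_cvs) array")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "data", arr)
        cols = self.columns
        if cols is None:
            cols = tuple(f"cv{i + 1}" for i in range(arr.shape[1]))
        else:
            cols = tuple(str(c) for c in cols)
            if len(cols) != arr.shape[1]:
                raise ValueError("number of column names does not match number of CVs")
        object.__setattr__(self, "columns", cols)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_cvs(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.columns))
        df.insert(0, "t", self.times)
        return df
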