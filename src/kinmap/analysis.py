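"""Descriptive layer: correlation screening and free-energy surfaces.

Pearson correlation tables relate candidate collective variables to
observables (e.g. backbone dihedral angles, hydrogen-bond distances) or one
coordinate set to another (e.g. diffusion-map vs. relaxation-mode
coordinates). Angle observables can optionally be embedded as sin/cos
before correlating, since plain Pearson on raw periodic angles is corrupted
by wrap-around at ±180°.

Free-energy surfaces are the standard −ln of the normalized 2-D histogram,
in units of kT (natural log), shifted so the occupied minimum is 0; empty
bins are masked, never assigned a value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import CVTrajectory


def _as_named_series(obj, default_prefix: str):
    """Accept a DataFrame, a mapping of name→1-D array, or a 2-D array."""
    if isinstance(obj, pd.DataFrame):
        return {str(c): np.asarray(obj[c], dtype=float) for c in obj.columns}
    if isinstance(obj, dict):
        return {str(k): np.asarray(v, dtype=float).ravel() for k, v in obj.items()}
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return {f"{default_prefix}{i + 1}": arr[:, i] for i in range(arr.shape[1])}


@dataclass(frozen=True)
class CorrelationTable:
    """Pearson coefficients, rows = CVs, columns = observables.

    ``r`` is a DataFrame; undefined pairs (zero variance) are NaN.
    ``sincos_used`` marks observables whose value is the max-|r| over their
    sine and cosine embeddings.
    """

    r: pd.DataFrame
    n_frames: int
    sincos_used: tuple = ()

    def to_tsv(self, path):
        self.r.to_csv(path, sep="\t", float_format="%.6g")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd = x - x.mean()
    yd = y - y.mean()
    nx = np.sqrt((xd * xd).sum())
    ny = np.sqrt((yd * yd).sum())
    if nx == 0.0 or ny == 0.0:
        return np.nan
    return float((xd * yd).sum() / (nx * ny))


def correlation_table(cvs, observables, angle_mode: str = "raw",
                      angle_columns=None, degrees: bool = False) -> CorrelationTable:
    """Pearson correlation of each CV against each observable.

    With ``angle_mode='sincos'``, observables listed in ``angle_columns``
    (all of them when None) are embedded as (sin, cos) and the coefficient
    of larger magnitude is reported; those columns are flagged in the
    result. ``degrees`` converts angle observables before embedding.
    """
    if angle_mode not in ("raw", "sincos"):
        raise ValueError("angle_mode must be 'raw' or 'sincos'")
    X = _as_named_series(cvs, "cv")
    Y = _as_named_series(observables, "obs")
    lengths = {len(v) for v in X.values()} | {len(v) for v in Y.values()}
    if len(lengths) != 1:
        raise ValueError("all series must have equal length")
    n = lengths.pop()
    if n < 3:
        raise ValueError("need at least 3 frames")
    for name, v in {**X, **Y}.items():
        if not np.all(np.isfinite(v)):
            raise ValueError(f"series {name!r} has non-finite values")
    if angle_mode == "sincos":
        angles = set(Y) if angle_columns is None else set(map(str, angle_columns))
        unknown = angles - set(Y)
        if unknown:
            raise ValueError(f"angle_columns not among observables: {sorted(unknown)}")
    else:
        angles = set()
    r = pd.DataFrame(index=list(X), columns=list(Y), dtype=float)
    for xn, xv in X.items():
        for yn, yv in Y.items():
            if yn in angles:
                ang = np.deg2rad(yv) if degrees else yv
                cands = [_pearson(xv, np.sin(ang)), _pearson(xv, np.cos(ang))]
                finite = [c for c in cands if np.isfinite(c)]
                r.loc[xn, yn] = (max(finite, key=abs) if finite else np.nan)
            else:
                r.loc[xn, yn] = _pearson(xv, yv)
    return CorrelationTable(r=r, n_frames=n, sincos_used=tuple(sorted(angles)))


def cross_correlation_matrix(set1, set2) -> CorrelationTable:
    """Correlation table between two coordinate sets (e.g. DM vs. RM)."""
    return correlation_table(set1, set2, angle_mode="raw")


@dataclass(frozen=True)
class FreeEnergySurface:
    """F = −ln(normalized density) over a 2-D grid, min over occupied = 0."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    F: np.ndarray          # (nx, ny); empty bins hold NaN
    occupied: np.ndarray   # boolean mask of occupied bins
    counts: np.ndarray

    @property
    def bin_centers(self):
        return (0.5 * (self.x_edges[1:] + self.x_edges[:-1]),
                0.5 * (self.y_edges[1:] + self.y_edges[:-1]))

    def local_minima(self, min_separation: float = 0.0):
        """Occupied bins that are ≤ all occupied 8-neighbours, sorted by F.

        With ``min_separation`` > 0 minima closer than that (in CV units)
        to an already-kept deeper minimum are suppressed, giving one
        representative per basin.
        """
        cx, cy = self.bin_centers
        nx, ny = self.F.shape
        cands = []
        for i in range(nx):
            for j in range(ny):
                if not self.occupied[i, j]:
                    continue
                is_min = True
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        a, b = i + di, j + dj
                        if 0 <= a < nx and 0 <= b < ny and self.occupied[a, b] \
                                and self.F[a, b] < self.F[i, j]:
                            is_min = False
                if is_min:
                    cands.append((self.F[i, j], cx[i], cy[j]))
        cands.sort()
        kept = []
        for f, x, y in cands:
            if all(np.hypot(x - kx, y - ky) >= min_separation for _, kx, ky in kept):
                kept.append((f, x, y))
        return kept

    def to_frame(self) -> pd.DataFrame:
        cx, cy = self.bin_centers
        xx, yy = np.meshgrid(cx, cy, indexing="ij")
        return pd.DataFrame({
            "x": xx.ravel(), "y": yy.ravel(),
            "F": self.F.ravel(), "occupied": self.occupied.ravel(),
        })


def free_energy_surface(samples, bins=50, ranges=None) -> FreeEnergySurface:
    """Free-energy surface from 2-D samples: F = −ln(count/total/binarea).

    The additive constant is fixed by shifting the occupied minimum to 0,
    so the surface is invariant (up to sampling noise) under changes of
    sample count at a fixed underlying distribution.
    """
    if isinstance(samples, CVTrajectory):
        pts = samples.data
    else:
        pts = np.asarray(samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
        raise ValueError("samples must be a nonempty (n, 2) array")
    counts, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=bins, range=ranges)
    occupied = counts > 0
    if not occupied.any():
        raise ValueError("no occupied bins in the requested range")
    area = np.outer(np.diff(xe), np.diff(ye))
    with np.errstate(divide="ignore"):
        F = -np.log(counts / counts.sum() / area)
    F[~occupied] = np.nan
    F -= np.nanmin(F)
    return FreeEnergySurface(x_edges=xe, y_edges=ye, F=F, occupied=occupied,
                             counts=counts.astype(np.int64))


def circular_correlation(a, b) -> float:
    """Fisher–Lee circular correlation of two angle series.

    ``r = Σ_{i<j} sin(a_i−a_j)·sin(b_i−b_j) / sqrt(Σ sin²(a_i−a_j) ·
    Σ sin²(b_i−b_j))``. Invariant under rotation of either series and well
    defined even for uniformly distributed angles (where mean-direction
    based variants degenerate); flips sign under reflection. Used to score
    angle recovery by embeddings, where the recovered angle is defined only
    up to an orthogonal transformation — compare absolute values.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length angle series of length >= 2")
    da = np.sin(a[:, None] - a[None, :])
    db = np.sin(b[:, None] - b[None, :])
    num = np.sum(da * db)
    denom = np.sqrt(np.sum(da ** 2) * np.sum(db ** 2))
    if denom == 0:
        return np.nan
    return float(num / denom)
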