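"""Diffusion-map embedding of CV samples, and short-time (windowed) maps.

Construction: a Gaussian kernel ``k(x_i, x_j) = exp(−||x_i − x_j||² / 2ε)``
over the samples is normalized into a row-stochastic matrix, either

* ``M_ij = k(x_i, x_j) / p(x_i)`` with ``p(x_i) = Σ_j k(x_i, x_j)``
  (``normalization='row'``, the default), or
* the density-corrected variant ``K_ij = k / (p(x_i) p(x_j))`` followed by
  the same row normalization (``'density_corrected'``).

Diagonalizing M gives 1 = λ₁ > λ₂ ≥ λ₃ ≥ …; the eigenvector u₁ is constant
and the diffusion-map coordinates are λ_α^t·u_α(x_i) with t = 1. Because M
is row-stochastic but not symmetric, eigenpairs are computed through the
symmetric conjugate D^{−1/2} K D^{−1/2} (D = kernel row sums), which shares
M's spectrum and yields stable real eigenvectors.

Short-time maps chop the trajectory into consecutive non-overlapping
windows, embed each window independently, and align each window's leading
nontrivial eigenvectors to a reference (typically the full-trajectory map)
by the sign-and-permutation maximizing total |Pearson r| over shared
frames — eigenvector sign and, near spectral crossings, eigenvector order
are otherwise arbitrary. The per-window standard deviation of each aligned
coordinate is the fluctuation series used to flag windows containing rare
transitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .trajectory import CVTrajectory

_CONNECTIVITY_TOL = 1e-12


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian-kernel bandwidth and normalization choice.

    ``epsilon`` is in squared CV units; ``None`` requests the default
    bandwidth (median nonzero pairwise squared distance of the data the
    kernel is built from).
    """

    epsilon: float = None
    normalization: str = "row"

    def __post_init__(self):
        if self.epsilon is not None and not (self.epsilon > 0):
            raise ValueError("epsilon must be positive")
        if self.normalization not in ("row", "density_corrected"):
            raise ValueError("normalization must be 'row' or 'density_corrected'")


def _as_points(data) -> np.ndarray:
    if isinstance(data, CVTrajectory):
        pts = data.data
    else:
        pts = np.asarray(data, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


def median_sq_distance(points) -> float:
    """Median of the nonzero pairwise squared Euclidean distances."""
    pts = _as_points(points)
    d2 = pdist(pts, metric="sqeuclidean")
    d2 = d2[d2 > 0]
    if d2.size == 0:
        raise ValueError("all points are identical; no usable bandwidth")
    return float(np.median(d2))


def gaussian_kernel(points, spec: KernelSpec) -> np.ndarray:
    """Dense symmetric kernel matrix exp(−d²/2ε), unit diagonal."""
    pts = _as_points(points)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    eps = spec.epsilon if spec.epsilon is not None else median_sq_distance(pts)
    d2 = squareform(pdist(pts, metric="sqeuclidean"))
    return np.exp(-d2 / (2.0 * eps))


def build_transition_matrix(kernel: np.ndarray, normalization: str = "row") -> np.ndarray:
    """Row-stochastic M from a kernel matrix, by either normalization."""
    K = np.asarray(kernel, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kernel must be square")
    p = K.sum(axis=1)
    if normalization == "row":
        return K / p[:, None]
    if normalization == "density_corrected":
        K2 = K / np.outer(p, p)
        return K2 / K2.sum(axis=1)[:, None]
    raise ValueError("normalization must be 'row' or 'density_corrected'")


@dataclass(frozen=True)
class DiffusionMapResult:
    """Eigenstructure of the diffusion-map transition matrix.

    ``eigenvectors`` holds right eigenvectors column-wise in descending
    eigenvalue order (u₁ first, constant); ``stationary`` is the left
    eigenvector of λ₁ = 1 normalized to sum 1, i.e. the sampled density.
    ``sample_indices`` are the original frame indices of the (possibly
    strided) samples the map was built from.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    stationary: np.ndarray
    epsilon: float
    sample_indices: np.ndarray
    normalization: str = "row"

    @property
    def n_samples(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_eigs(self) -> int:
        return self.eigenvalues.size

    def coordinates(self, t: float = 1.0) -> np.ndarray:
        """Diffusion-map coordinates λ_α^t·u_α(x_i), columns α = 1..k."""
        return (self.eigenvalues ** t) * self.eigenvectors

    @property
    def dm_coordinates(self) -> np.ndarray:
        return self.coordinates(t=1.0)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-|entry| component of each column > 0."""
    U = U.copy()
    for k in range(U.shape[1]):
        j = int(np.argmax(np.abs(U[:, k])))
        if U[j, k] < 0:
            U[:, k] = -U[:, k]
    return U


def _eig_from_kernel(K: np.ndarray, n_eigs: int, normalization: str):
    """Top eigenpairs of the row-normalized kernel via the symmetric conjugate."""
    if normalization == "density_corrected":
        p = K.sum(axis=1)
        K = K / np.outer(p, p)
    d = K.sum(axis=1)
    dsq = np.sqrt(d)
    S = K / np.outer(dsq, dsq)
    S = 0.5 * (S + S.T)
    n = S.shape[0]
    w, V = eigh(S, subset_by_index=[n - n_eigs, n - 1])
    w = w[::-1]
    V = V[:, ::-1]
    U = V / dsq[:, None]
    # scale right eigenvectors to unit Euclidean norm
    U = U / np.linalg.norm(U, axis=0)
    U = _fix_signs(U)
    stationary = d / d.sum()
    return w, U, stationary


def diffusion_map(data, spec: KernelSpec = None, n_eigs: int = 4,
                  stride: int = 1) -> DiffusionMapResult:
    """Diffusion-map embedding of a trajectory or point set.

    ``stride`` subsamples the frames before building the (dense) kernel;
    with N retained samples the cost is O(N²) memory and O(N³) time.
    Raises if the kernel graph is numerically disconnected (multiple unit
    eigenvalues), which signals an ε too small for the data's gaps.
    """
    spec = spec or KernelSpec()
    if stride < 1:
        raise ValueError("stride must be >= 1")
    pts = _as_points(data)[::stride]
    if pts.shape[0] < n_eigs + 1:
        raise ValueError(f"need at least n_eigs+1 = {n_eigs + 1} samples, "
                         f"got {pts.shape[0]} after striding")
    eps = spec.epsilon if spec.epsilon is not None else median_sq_distance(pts)
    K = gaussian_kernel(pts, KernelSpec(epsilon=eps, normalization=spec.normalization))
    w, U, stat = _eig_from_kernel(K, n_eigs, spec.normalization)
    if w.size > 1 and (1.0 - w[1]) < _CONNECTIVITY_TOL:
        raise ValueError(
            "kernel graph is numerically disconnected (repeated unit "
            "eigenvalue); increase epsilon"
        )
    return DiffusionMapResult(eigenvalues=w, eigenvectors=U, stationary=stat,
                              epsilon=eps,
                              sample_indices=np.arange(0, _as_points(data).shape[0],
                                                       stride),
                              normalization=spec.normalization)


def select_epsilon(points, candidates=None):
    """Default bandwidth plus the kernel-sum diagnostic curve.

    The returned ε is the median nonzero pairwise squared distance. The
    diagnostic table tabulates ``S(ε) = Σ_ij k(x_i, x_j)`` over a log-spaced
    candidate grid together with the local log–log slope
    d log S / d log ε; S saturates at N (ε→0) and N² (ε→∞), and the
    maximum-slope region marks the scale range where the kernel resolves
    the data — the standard aid for overriding the default.

    Returns ``(epsilon, table)`` with table columns
    ``epsilon, kernel_sum, slope, max_slope_region``.
    """
    pts = _as_points(points)
    eps0 = median_sq_distance(pts)
    if candidates is None:
        candidates = eps0 * np.logspace(-3, 3, 25)
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size < 2 or candidates[-1] / candidates[0] < 100:
        raise ValueError("candidate grid must span at least two decades "
                         "with >= 2 values")
    d2 = pdist(pts, metric="sqeuclidean")
    n = pts.shape[0]
    sums = np.array([n + 2.0 * np.exp(-d2 / (2.0 * e)).sum() for e in candidates])
    logs = np.log(sums)
    loge = np.log(candidates)
    slope = np.gradient(logs, loge)
    in_max = slope >= 0.9 * slope.max() if slope.max() > 0 else np.zeros(len(slope), bool)
    table = pd.DataFrame({"epsilon": candidates, "kernel_sum": sums,
                          "slope": slope, "max_slope_region": in_max})
    return eps0, table


@dataclass(frozen=True)
class WindowedDMResult:
    """Per-window diffusion maps with alignment and fluctuation series.

    ``permutations[w, i]`` gives the window-w eigenvector column assigned to
    aligned slot i (slots index the nontrivial eigenvectors α = 2..k), and
    ``signs[w, i]`` its orientation. ``fluctuations[w, i]`` is the standard
    deviation over the window of aligned DM coordinate i (λ·u scale).
    """

    window_length: int
    results: tuple
    permutations: np.ndarray
    signs: np.ndarray
    fluctuations: np.ndarray
    window_starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.results)

    def aligned_coordinates(self, w: int) -> np.ndarray:
        """Aligned nontrivial DM coordinates of window w (frames × slots)."""
        res = self.results[w]
        coords = res.dm_coordinates[:, 1:]
        return coords[:, self.permutations[w]] * self.signs[w]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in range(self.n_windows):
            rec = {"window": w, "start_frame": int(self.window_starts[w])}
            for i in range(self.fluctuations.shape[1]):
                rec[f"fluct_dm{i + 2}"] = self.fluctuations[w, i]
            rows.append(rec)
        return pd.DataFrame(rows)


def _correlation_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between columns of A and columns of B."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    return (A.T @ B) / np.outer(na, nb)


def _align_to_reference(win_vecs, win_idx, ref_vecs, ref_idx):
    """Sign-and-permutation alignment by total |Pearson r| over shared frames.

    Returns (perm, signs, r_assigned): aligned slot i uses window column
    perm[i] with orientation signs[i].
    """
    common, ia, ib = np.intersect1d(win_idx, ref_idx, return_indices=True)
    if common.size < 3:
        raise ValueError("fewer than 3 shared frames between window and reference; "
                         "use a denser reference stride")
    C = _correlation_matrix(ref_vecs[ib], win_vecs[ia])
    ref_slots, win_cols = linear_sum_assignment(-np.abs(C))
    perm = np.empty(C.shape[0], dtype=int)
    signs = np.empty(C.shape[0])
    r = np.empty(C.shape[0])
    for i, j in zip(ref_slots, win_cols):
        perm[i] = j
        r[i] = C[i, j]
        signs[i] = 1.0 if C[i, j] >= 0 else -1.0
    return perm, signs, r


def short_time_dm(traj, spec: KernelSpec = None, window_length: int = 100,
                  n_eigs: int = 3, reference=None) -> WindowedDMResult:
    """Windowed diffusion maps over consecutive non-overlapping windows.

    ``reference`` may be a full-trajectory :class:`DiffusionMapResult`
    (alignment over shared frames), the string ``'previous'`` (each window
    aligned to the previous aligned window, matched through
    nearest-neighbour lookup in CV space since consecutive windows share no
    frames), or None (per-window sign convention only, identity
    permutation). A single fixed ε — the spec's, or the full-trajectory
    median squared distance — is used for every window so fluctuation
    amplitudes are comparable across windows.
    """
    spec = spec or KernelSpec()
    pts = _as_points(traj)
    if window_length < n_eigs + 1:
        raise ValueError(f"window_length must be >= n_eigs+1 = {n_eigs + 1}")
    n_windows = pts.shape[0] // window_length
    if n_windows < 1:
        raise ValueError("trajectory shorter than one window")
    eps = spec.epsilon if spec.epsilon is not None else median_sq_distance(pts)
    wspec = KernelSpec(epsilon=eps, normalization=spec.normalization)
    k = n_eigs - 1  # nontrivial eigenvectors to align

    results = []
    perms = np.empty((n_windows, k), dtype=int)
    signs = np.ones((n_windows, k))
    flucts = np.empty((n_windows, k))
    starts = np.arange(n_windows) * window_length
    prev_pts = None
    prev_aligned_vecs = None
    for w in range(n_windows):
        lo = int(starts[w])
        win = pts[lo:lo + window_length]
        res = diffusion_map(win, wspec, n_eigs=n_eigs, stride=1)
        res = DiffusionMapResult(eigenvalues=res.eigenvalues,
                                 eigenvectors=res.eigenvectors,
                                 stationary=res.stationary,
                                 epsilon=res.epsilon,
                                 sample_indices=res.sample_indices + lo,
                                 normalization=res.normalization)
        if isinstance(reference, DiffusionMapResult):
            perm, sgn, _ = _align_to_reference(
                res.eigenvectors[:, 1:], res.sample_indices,
                reference.eigenvectors[:, 1:1 + k], reference.sample_indices)
        elif reference == "previous" and prev_pts is not None:
            tree = cKDTree(prev_pts)
            _, nn = tree.query(win)
            perm, sgn, _ = _align_to_reference(
                res.eigenvectors[:, 1:], np.arange(window_length),
                prev_aligned_vecs[nn], np.arange(window_length))
        elif reference not in (None, "previous"):
            raise ValueError("reference must be a DiffusionMapResult, "
                             "'previous', or None")
        else:
            perm = np.arange(k)
            sgn = np.ones(k)
        perms[w] = perm
        signs[w] = sgn
        coords = res.dm_coordinates[:, 1:][:, perm] * sgn
        flucts[w] = coords.std(axis=0)
        results.append(res)
        prev_pts = win
        prev_aligned_vecs = res.eigenvectors[:, 1:][:, perm] * sgn
    return WindowedDMResult(window_length=window_length, results=tuple(results),
                            permutations=perms, signs=signs,
                            fluctuations=flucts, window_starts=starts)
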