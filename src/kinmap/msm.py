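"""Conventional Markov-state-model estimation and first-passage analysis.

The model is the row-stochastic transition matrix at a fixed lag time,

    T_ij = N_ij / Σ_j N_ij ,

where N counts observed pairs (state at t, state at t+lag) sliding over
every valid frame. From T the package computes

* the equilibrium population (left unit eigenvector of T),
* mean first passage times by the linear system
  ``F_if = 1 + Σ_{j≠f} T_ij F_jf`` (time in lag units, converted to
  physical time via lag × frame_interval), and
* first-passage-time distributions by the absorbing-chain recursion
  ``f_ij(1) = T_ij``, ``f_ij(n) = Σ_{k≠j} T_ik f_kj(n−1)``.

Counts are used raw: rows are never symmetrized and no detailed balance is
enforced, so non-reversibility in the data is preserved. States never
visited at the start of a counted pair are dropped with a warning rather
than regularized with pseudocounts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components

from .states import UNASSIGNED, LabelSequence

_ROW_TOL = 1e-12


def count_transitions(labels, lag: int = 1, include_unassigned: bool = True,
                      states=None):
    """Enumerate the counting matrix N at the given lag.

    Every frame pair ``(t, t+lag)`` is counted (sliding window). Unassigned
    frames form an explicit extra state (named ``U``) when
    ``include_unassigned`` is true; otherwise pairs touching an unassigned
    frame are skipped. ``states`` restricts counting to a subset of labels.

    Returns
    -------
    N : (n, n) integer array
    states : list of the integer labels indexing N's rows/columns
    """
    if isinstance(labels, LabelSequence):
        lab = labels.labels
    else:
        lab = np.asarray(labels, dtype=np.int64)
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if lag >= lab.size:
        raise ValueError(f"lag {lag} must be smaller than sequence length {lab.size}")
    a = lab[:-lag]
    b = lab[lag:]
    if states is not None:
        keep = np.isin(a, states) & np.isin(b, states)
        a, b = a[keep], b[keep]
        state_list = [int(s) for s in states]
    else:
        if not include_unassigned:
            keep = (a != UNASSIGNED) & (b != UNASSIGNED)
            a, b = a[keep], b[keep]
        state_list = sorted(set(np.unique(a).tolist()) | set(np.unique(b).tolist()))
    if a.size == 0:
        raise ValueError("no usable frame pairs to count")
    index = {s: k for k, s in enumerate(state_list)}
    n = len(state_list)
    ia = np.vectorize(index.__getitem__, otypes=[np.int64])(a)
    ib = np.vectorize(index.__getitem__, otypes=[np.int64])(b)
    N = np.bincount(ia * n + ib, minlength=n * n).reshape(n, n)
    return N, state_list


@dataclass(frozen=True)
class TransitionModel:
    """Counting matrix, row-stochastic T, lag and time metadata.

    ``N`` may be None for analytically specified matrices (see
    :meth:`from_stochastic`); when present, T must equal N normalized
    row-wise.
    """

    T: np.ndarray
    N: np.ndarray = None
    lag: int = 1
    frame_interval: float = 1.0
    states: tuple = None          # original integer labels per row
    state_names: tuple = None     # printable names per row

    def __post_init__(self):
        T = np.asarray(self.T, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("T must be square")
        if (T < 0).any():
            raise ValueError("T has negative entries")
        rows = T.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > _ROW_TOL:
            raise ValueError("T rows must sum to 1 within 1e-12")
        if self.lag < 1 or self.frame_interval <= 0:
            raise ValueError("lag must be >= 1 and frame_interval positive")
        n = T.shape[0]
        if self.N is not None:
            N = np.asarray(self.N)
            if N.shape != T.shape or (N < 0).any():
                raise ValueError("N must match T's shape with nonnegative entries")
            rs = N.sum(axis=1)
            if (rs == 0).any():
                raise ValueError("N has a zero row; drop unvisited states first")
            if np.max(np.abs(N / rs[:, None] - T)) > 1e-10:
                raise ValueError("T is not the row normalization of N")
            object.__setattr__(self, "N", N)
        states = tuple(self.states) if self.states is not None else tuple(range(n))
        names = (tuple(self.state_names) if self.state_names is not None
                 else tuple("U" if s == UNASSIGNED else str(s) for s in states))
        if len(states) != n or len(names) != n:
            raise ValueError("states/state_names length must match T")
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "state_names", names)

    @classmethod
    def from_stochastic(cls, T, lag: int = 1, frame_interval: float = 1.0,
                        state_names=None) -> "TransitionModel":
        """Wrap an analytically specified row-stochastic matrix (no counts)."""
        return cls(T=np.asarray(T, dtype=float), N=None, lag=lag,
                   frame_interval=frame_interval, state_names=state_names)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def time_unit(self) -> float:
        """Physical time per lag step."""
        return self.lag * self.frame_interval

    def index(self, state) -> int:
        """Resolve a state (row position, original label, or name) to a row index."""
        if isinstance(state, str):
            return self.state_names.index(state)
        s = int(state)
        if s in self.states:
            return self.states.index(s)
        raise ValueError(f"state {state!r} not in model states {self.states}")


def transition_matrix(N, states=None, lag: int = 1, frame_interval: float = 1.0,
                      state_names=None) -> TransitionModel:
    """Row-normalize a counting matrix into a :class:`TransitionModel`.

    Rows (states) with zero outgoing counts are dropped with a warning;
    their columns are removed as well and remaining rows renormalized over
    the retained states.
    """
    N = np.asarray(N)
    if N.ndim != 2 or N.shape[0] != N.shape[1] or (N < 0).any():
        raise ValueError("N must be a square nonnegative matrix")
    n = N.shape[0]
    if states is None:
        states = list(range(n))
    if state_names is None:
        state_names = ["U" if s == UNASSIGNED else str(s) for s in states]
    rowsums = N.sum(axis=1)
    keep = rowsums > 0
    if not keep.any():
        raise ValueError("every row of N is empty")
    if not keep.all():
        dropped = [state_names[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping unvisited states with zero outgoing counts: {dropped}")
        N = N[np.ix_(keep, keep)]
        states = [s for s, k in zip(states, keep) if k]
        state_names = [nm for nm, k in zip(state_names, keep) if k]
        rowsums = N.sum(axis=1)
        if (rowsums == 0).any():
            raise ValueError("dropping unvisited states emptied a remaining row")
    T = N / rowsums[:, None]
    return TransitionModel(T=T, N=N, lag=lag, frame_interval=frame_interval,
                           states=tuple(states), state_names=tuple(state_names))


def estimate(labels, lag: int = 1, frame_interval: float = None,
             include_unassigned: bool = True, states=None) -> TransitionModel:
    """Count transitions and build the transition model in one step."""
    if frame_interval is None:
        frame_interval = labels.frame_interval if isinstance(labels, LabelSequence) else 1.0
    N, state_list = count_transitions(labels, lag=lag,
                                      include_unassigned=include_unassigned,
                                      states=states)
    names = None
    if isinstance(labels, LabelSequence) and labels.state_names is not None:
        names = [labels.name_of(s) for s in state_list]
    return transition_matrix(N, states=state_list, lag=lag,
                             frame_interval=frame_interval, state_names=names)


def equilibrium_population(model: TransitionModel) -> np.ndarray:
    """Stationary distribution: left eigenvector of T for eigenvalue 1.

    Requires an irreducible T; otherwise the stationary vector is not
    unique and the disconnected blocks are reported in the error.
    """
    T = model.T
    ncomp, comp = connected_components(csr_matrix(T > 0), directed=True,
                                       connection="strong")
    if ncomp > 1:
        blocks = [tuple(np.array(model.state_names)[comp == c]) for c in range(ncomp)]
        raise ValueError(f"transition matrix is reducible; strongly connected "
                         f"blocks: {blocks}")
    w, vl = sla.eig(T, left=True, right=False)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _reachability_check(T: np.ndarray, target: int, names) -> None:
    # states from which `target` is reachable = BFS from target on T^T
    order = breadth_first_order(csr_matrix((T > 0).T), target,
                                return_predecessors=False)
    reachable = set(np.atleast_1d(order).tolist())
    bad = [names[i] for i in range(T.shape[0]) if i not in reachable]
    if bad:
        raise ValueError(f"target {names[target]!r} unreachable from states {bad}")


def _mfpt_lag_units(T: np.ndarray, target: int, names=None) -> np.ndarray:
    """Solve ``F = 1 + Q F`` over non-target states; F[target] = 0."""
    n = T.shape[0]
    if names is None:
        names = [str(i) for i in range(n)]
    _reachability_check(T, target, names)
    idx = [i for i in range(n) if i != target]
    Q = T[np.ix_(idx, idx)]
    F = np.linalg.solve(np.eye(len(idx)) - Q, np.ones(len(idx)))
    out = np.zeros(n)
    out[idx] = F
    return out


def mfpt(model: TransitionModel, target) -> np.ndarray:
    """Mean first passage time from every state to ``target``, in physical
    time (lag units × lag × frame_interval). The target entry is 0 by the
    convention that the walker is already there."""
    t = model.index(target)
    return _mfpt_lag_units(model.T, t, model.state_names) * model.time_unit


@dataclass(frozen=True)
class FPTDistribution:
    """First-passage-time distribution f(n), n = 1..n_max (lag steps).

    ``tail_mass`` is the probability of first passage beyond n_max;
    probabilities plus tail mass sum to 1. ``mean`` is the full
    Σ n·f(n) expectation in physical time units: the stored range
    contributes exactly, and the tail contributes its exact conditional
    expectation ``Σ_k ρ_k·(n_max + F_k)`` computed from the residual
    distribution ρ over transient states at step n_max and the linear-solve
    MFPTs F (infinite when the target is not almost-surely reached).
    """

    probabilities: np.ndarray
    lag: int
    frame_interval: float
    tail_mass: float
    mean: float
    source: int = 0
    target: int = 1

    @property
    def n_max(self) -> int:
        return self.probabilities.size

    @property
    def steps(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)

    @property
    def times(self) -> np.ndarray:
        """Physical times of the stored steps."""
        return self.steps * self.lag * self.frame_interval

    @property
    def mean_lag_units(self) -> float:
        return self.mean / (self.lag * self.frame_interval)


def _fptd_lag_units(T: np.ndarray, source: int, target: int, n_max: int):
    """Recursion f(n) plus residual distribution at n_max.

    Implemented as repeated application of T with the target column zeroed
    (the absorbing-chain formulation): with g_k(n) = f_kj(n),
    g(1) = T[:, j] and g(n) = T0 @ g(n−1).
    """
    T0 = T.copy()
    T0[:, target] = 0.0
    g = T[:, target].copy()          # f_kj(1) for all k
    rho = np.zeros(T.shape[0])       # residual (not yet absorbed) from `source`
    rho[source] = 1.0
    f = np.empty(n_max)
    f[0] = g[source]
    rho = rho @ T0
    for n in range(1, n_max):
        g = T0 @ g
        f[n] = g[source]
        rho = rho @ T0
    return f, rho


def fpt_distribution(model: TransitionModel, source, target,
                     n_max: int = 10000) -> FPTDistribution:
    """First-passage-time distribution from ``source`` to ``target``.

    ``f(1) = T[source, target]`` exactly; subsequent values follow the
    recursion. The mean includes the exact tail correction described on
    :class:`FPTDistribution`.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    i = model.index(source)
    j = model.index(target)
    f, rho = _fptd_lag_units(model.T, i, j, n_max)
    tail = float(rho.sum())
    mean_lag = float(np.arange(1, n_max + 1) @ f)
    if tail > 1e-300:
        try:
            F = _mfpt_lag_units(model.T, j, model.state_names)
            mean_lag += float(rho @ (n_max + F))
        except ValueError:
            mean_lag = np.inf
    return FPTDistribution(probabilities=f, lag=model.lag,
                           frame_interval=model.frame_interval,
                           tail_mass=tail, mean=mean_lag * model.time_unit,
                           source=i, target=j)
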