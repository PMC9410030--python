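"""History-augmented ("non-Markov") transition analysis for a core pair.

For a designated ordered pair of cores (A, B) the trajectory is annotated
with the last-visited element of {A, B}; transition pairs are then counted
*conditioned on the history being A*, and the target B is made absorbing.
For a three-block layout (A, intermediate I, B) the conditional matrix is

        [ T_AA^{AA}  T_AI^{AA}  T_AB^{AB} ]
    T = [ T_IA^{AA}  T_II^{AA}  T_IB^{AB} ]
        [    0          0           1     ]

whose first-passage distribution and MFPT are computed exactly as for a
conventional MSM. Because intermediate frames remember which core they came
from, lumped or poorly resolved intermediates no longer bias the A→B
kinetics the way they bias a plain MSM.

Frames before the first visit to either core have undefined history and are
excluded from counting. The reverse direction (B→A) is an independent second
pass with the pair swapped; nothing is shared between directions, so forward
and backward MFPTs are free to differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .msm import FPTDistribution, _fptd_lag_units, _mfpt_lag_units
from .states import UNASSIGNED, LabelSequence

#: History value for frames preceding the first visit to either core.
HISTORY_UNDEFINED = -2


@dataclass(frozen=True)
class HistoryLabeledSequence:
    """Labels plus the per-frame last-visited core of the designated pair."""

    labels: np.ndarray
    history: np.ndarray
    pair: tuple
    frame_interval: float = 1.0
    state_names: tuple = None

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=np.int64)
        his = np.asarray(self.history, dtype=np.int64)
        if lab.shape != his.shape or lab.ndim != 1:
            raise ValueError("labels and history must be equal-length 1-D arrays")
        a, b = self.pair
        ok = np.isin(his, [a, b, HISTORY_UNDEFINED])
        if not ok.all():
            raise ValueError("history entries must be A, B, or undefined")
        if np.any((lab == a) & (his != a)) or np.any((lab == b) & (his != b)):
            raise ValueError("history must equal the label on core frames")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "history", his)
        object.__setattr__(self, "pair", (int(a), int(b)))


def label_history(labels, pair) -> HistoryLabeledSequence:
    """Annotate each frame with the last-visited element of ``pair``.

    ``pair`` may contain integer labels or state names (resolved through the
    sequence's ``state_names``). Both cores must occur in the sequence.
    """
    if isinstance(labels, LabelSequence):
        lab = labels.labels
        fi = labels.frame_interval
        names = labels.state_names
        a, b = (labels.index(p) for p in pair)
    else:
        lab = np.asarray(labels, dtype=np.int64)
        fi = 1.0
        names = None
        a, b = (int(p) for p in pair)
    if a == b:
        raise ValueError("pair must name two distinct cores")
    for core in (a, b):
        if not np.any(lab == core):
            raise ValueError(f"core {core} never visited in the sequence")
    n = lab.size
    on_core = (lab == a) | (lab == b)
    pos = np.where(on_core, np.arange(n), -1)
    last = np.maximum.accumulate(pos)
    history = np.where(last >= 0, lab[np.maximum(last, 0)], HISTORY_UNDEFINED)
    return HistoryLabeledSequence(labels=lab, history=history, pair=(a, b),
                                  frame_interval=fi, state_names=names)


@dataclass(frozen=True)
class ConditionalTransitionModel:
    """Conditional (history = A) transition matrix with absorbing target B.

    Rows/columns are laid out ``[A, intermediates..., B]``; ``row_states``
    gives each row's meaning (the label integer for A/B and kept
    intermediates, or the string ``"I"`` for the lumped intermediate
    block). The last row is exactly (0, ..., 0, 1).
    """

    pair: tuple
    T_cond: np.ndarray
    counts: np.ndarray
    row_states: tuple
    lag: int = 1
    frame_interval: float = 1.0
    intermediate_mode: str = "lump"
    state_names: tuple = None

    def __post_init__(self):
        T = np.asarray(self.T_cond, dtype=float)
        n = T.shape[0]
        if T.ndim != 2 or T.shape[1] != n or n < 2:
            raise ValueError("T_cond must be square with at least 2 states")
        if (T < 0).any():
            raise ValueError("T_cond has negative entries")
        if np.max(np.abs(T[:-1].sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transient rows must sum to 1 within 1e-12")
        absorbing = np.zeros(n)
        absorbing[-1] = 1.0
        if not np.array_equal(T[-1], absorbing):
            raise ValueError("target row must be exactly (0, ..., 0, 1)")
        if len(self.row_states) != n:
            raise ValueError("row_states length must match T_cond")
        object.__setattr__(self, "T_cond", T)
        object.__setattr__(self, "row_states", tuple(self.row_states))
        object.__setattr__(self, "pair", tuple(int(p) for p in self.pair))

    @property
    def n_states(self) -> int:
        return self.T_cond.shape[0]

    @property
    def time_unit(self) -> float:
        return self.lag * self.frame_interval

    @property
    def row_names(self) -> tuple:
        def nm(s):
            if isinstance(s, str):
                return s
            if s == UNASSIGNED:
                return "U"
            if self.state_names is not None:
                return self.state_names[s]
            return str(s)
        return tuple(nm(s) for s in self.row_states)


def conditional_transition_matrix(hist: HistoryLabeledSequence, lag: int = 1,
                                  intermediate_mode: str = "lump"
                                  ) -> ConditionalTransitionModel:
    """Count conditional transitions with history = A and absorbing B.

    Pairs ``(t, t+lag)`` are counted only when ``history(t) = A`` (so the
    start frame is A itself or an intermediate reached from A). With
    ``intermediate_mode='lump'`` every non-A, non-B label (including
    unassigned frames) forms a single intermediate block, matching the
    three-block layout above; ``'keep'`` retains each intermediate label as
    its own row. Empty transient rows are dropped with a warning.
    """
    if intermediate_mode not in ("lump", "keep"):
        raise ValueError("intermediate_mode must be 'lump' or 'keep'")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    a, b = hist.pair
    lab = hist.labels
    if lag >= lab.size:
        raise ValueError("lag must be smaller than the sequence length")
    start = lab[:-lag]
    end = lab[lag:]
    mask = hist.history[:-lag] == a
    if not mask.any():
        raise ValueError(f"no frames with history {a}; cannot condition on it")
    start = start[mask]
    end = end[mask]

    if intermediate_mode == "lump":
        inter_states: list = ["I"] if np.any((start != a) | ((end != a) & (end != b))) else []
        def classify(x):
            out = np.full(x.shape, 1, dtype=np.int64)  # intermediate slot
            out[x == a] = 0
            out[x == b] = 2
            return out
        n_inter = len(inter_states)
        row_states = [a] + inter_states + [b]
        ia_codes = classify(start)
        ib_codes = classify(end)
        if n_inter == 0 and (np.any(ia_codes == 1) or np.any(ib_codes == 1)):
            raise AssertionError("unreachable: intermediate frames present")
        ia = np.where(ia_codes == 0, 0, np.where(ia_codes == 2, 1 + n_inter, 1))
        ib = np.where(ib_codes == 0, 0, np.where(ib_codes == 2, 1 + n_inter, 1))
    else:
        seen = set(np.unique(start).tolist()) | set(np.unique(end).tolist())
        others = sorted(s for s in seen if s not in (a, b))
        row_states = [a] + others + [b]
        index = {s: k for k, s in enumerate(row_states)}
        ia = np.vectorize(index.__getitem__, otypes=[np.int64])(start)
        ib = np.vectorize(index.__getitem__, otypes=[np.int64])(end)

    n = len(row_states)
    counts = np.bincount(ia * n + ib, minlength=n * n).reshape(n, n).astype(np.int64)
    # B rows never occur as starts (their history is B); enforce absorption.
    counts[-1] = 0

    rowsums = counts[:-1].sum(axis=1)
    if rowsums[0] == 0:
        raise ValueError(f"no counted transitions out of core {a}")
    keep = np.concatenate([rowsums > 0, [True]])
    if not keep.all():
        dropped = [row_states[i] for i in np.flatnonzero(~keep)]
        warnings.warn(f"dropping empty transient rows: {dropped}")
        counts = counts[np.ix_(keep, keep)]
        row_states = [s for s, k in zip(row_states, keep) if k]
        rowsums = counts[:-1].sum(axis=1)
        if (rowsums == 0).any():
            raise ValueError("dropping empty rows emptied another transient row")
    n = len(row_states)
    T = np.zeros((n, n))
    T[:-1] = counts[:-1] / rowsums[:, None]
    T[-1, -1] = 1.0
    return ConditionalTransitionModel(pair=(a, b), T_cond=T, counts=counts,
                                      row_states=tuple(row_states), lag=lag,
                                      frame_interval=hist.frame_interval,
                                      intermediate_mode=intermediate_mode,
                                      state_names=hist.state_names)


def nonmarkov_mfpt(model: ConditionalTransitionModel) -> float:
    """MFPT A→B from the conditional matrix (physical time units)."""
    F = _mfpt_lag_units(model.T_cond, model.n_states - 1, model.row_names)
    return float(F[0]) * model.time_unit


def nonmarkov_fptd(model: ConditionalTransitionModel,
                   n_max: int = 10000) -> FPTDistribution:
    """First-passage-time distribution A→B from the conditional matrix.

    Same recursion and exact tail correction as the MSM path;
    ``f(1) = T_cond[A, B]`` exactly.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    j = model.n_states - 1
    f, rho = _fptd_lag_units(model.T_cond, 0, j, n_max)
    tail = float(rho.sum())
    mean_lag = float(np.arange(1, n_max + 1) @ f)
    if tail > 1e-300:
        try:
            F = _mfpt_lag_units(model.T_cond, j, model.row_names)
            mean_lag += float(rho @ (n_max + F))
        except ValueError:
            mean_lag = np.inf
    return FPTDistribution(probabilities=f, lag=model.lag,
                           frame_interval=model.frame_interval,
                           tail_mass=tail, mean=mean_lag * model.time_unit,
                           source=0, target=j)


def analyze_pair(labels, pair, lag: int = 1, intermediate_mode: str = "lump",
                 n_max: int = 10000):
    """Forward and backward non-Markov analysis of an ordered core pair.

    Returns a dict with keys ``forward`` and ``backward``, each holding the
    conditional model, its MFPT (time units), and its FPTD.
    """
    out = {}
    for key, p in (("forward", tuple(pair)), ("backward", tuple(pair)[::-1])):
        hist = label_history(labels, p)
        model = conditional_transition_matrix(hist, lag=lag,
                                              intermediate_mode=intermediate_mode)
        out[key] = {
            "pair": model.pair,
            "model": model,
            "mfpt": nonmarkov_mfpt(model),
            "fptd": nonmarkov_fptd(model, n_max=n_max),
        }
    return out
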