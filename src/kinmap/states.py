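"""Metastable cores in CV space and per-frame discrete state labels.

A *core* is a disk (hypersphere) of given radius around a center in CV
space; frames outside every core carry the reserved unassigned label −1
("unfolded"). Cores must be pairwise disjoint, so assignment is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import CVTrajectory

#: Reserved label for frames outside every core.
UNASSIGNED = -1


@dataclass(frozen=True)
class Core:
    name: str
    center: np.ndarray
    radius: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.ndim != 1:
            raise ValueError(f"core {self.name!r}: center must be a 1-D vector")
        if not np.all(np.isfinite(c)):
            raise ValueError(f"core {self.name!r}: non-finite center")
        if not (self.radius > 0):
            raise ValueError(f"core {self.name!r}: radius must be positive")
        object.__setattr__(self, "center", c)


@dataclass(frozen=True)
class StateDefinition:
    """An ordered set of disjoint named cores.

    Disjointness (center separation strictly greater than the sum of radii)
    is enforced at construction so every point lies in at most one core.
    """

    cores: tuple
    unassigned_label: int = UNASSIGNED

    def __post_init__(self):
        cores = tuple(self.cores)
        if not cores:
            raise ValueError("at least one core is required")
        names = [c.name for c in cores]
        if len(set(names)) != len(names):
            raise ValueError(f"core names must be unique, got {names}")
        dims = {c.center.shape[0] for c in cores}
        if len(dims) != 1:
            raise ValueError("all core centers must have the same dimensionality")
        for i in range(len(cores)):
            for j in range(i + 1, len(cores)):
                d = float(np.linalg.norm(cores[i].center - cores[j].center))
                if d <= cores[i].radius + cores[j].radius:
                    raise ValueError(
                        f"cores {cores[i].name!r} and {cores[j].name!r} overlap: "
                        f"center distance {d:.4g} <= radius sum "
                        f"{cores[i].radius + cores[j].radius:.4g}"
                    )
        object.__setattr__(self, "cores", cores)

    @property
    def n_cores(self) -> int:
        return len(self.cores)

    @property
    def names(self) -> tuple:
        return tuple(c.name for c in self.cores)

    @property
    def dim(self) -> int:
        return self.cores[0].center.shape[0]

    def index(self, name):
        """Resolve a core name or integer label to a label integer."""
        if isinstance(name, (int, np.integer)):
            return int(name)
        return self.names.index(name)

    @classmethod
    def folding_three_state(cls, radius: float = 1.4) -> "StateDefinition":
        """Folded / misfolded / intermediate cores of a chignolin-like
        two-dimensional landscape: centers (−3, 0), (3, −5), (2, 2)."""
        return cls(cores=(
            Core("F", np.array([-3.0, 0.0]), radius),
            Core("M", np.array([3.0, -5.0]), radius),
            Core("I", np.array([2.0, 2.0]), radius),
        ))


@dataclass(frozen=True)
class LabelSequence:
    """Per-frame integer state labels at a fixed frame interval.

    Labels are core indices ``0..n_cores−1`` or :data:`UNASSIGNED`.
    ``n_cores`` records how many cores were defined (labels that happen never
    to occur still count), so occupancy vectors have a stable length.
    """

    labels: np.ndarray
    frame_interval: float = 1.0
    n_cores: int = None
    state_names: tuple = None

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=np.int64)
        if lab.ndim != 1 or lab.size < 1:
            raise ValueError("labels must be a nonempty 1-D integer sequence")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        n_cores = self.n_cores
        if n_cores is None:
            n_cores = int(lab.max()) + 1 if lab.max() >= 0 else 0
        bad = (lab < 0) & (lab != UNASSIGNED)
        if bad.any() or (lab >= n_cores).any():
            raise ValueError(f"labels must lie in {{0..{n_cores - 1}}} or {UNASSIGNED}")
        names = self.state_names
        if names is not None:
            names = tuple(names)
            if len(names) != n_cores:
                raise ValueError("state_names length must equal n_cores")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "n_cores", int(n_cores))
        object.__setattr__(self, "state_names", names)

    def __len__(self):
        return self.labels.size

    def name_of(self, label: int) -> str:
        if label == UNASSIGNED:
            return "U"
        if self.state_names is not None:
            return self.state_names[label]
        return str(label)

    def index(self, state):
        """Resolve a state name or integer to its label integer."""
        if isinstance(state, (int, np.integer)):
            return int(state)
        if state == "U":
            return UNASSIGNED
        if self.state_names is None:
            raise ValueError("no state names attached to this sequence")
        return self.state_names.index(state)


def assign_states(traj: CVTrajectory, defn: StateDefinition) -> LabelSequence:
    """Assign each frame to the core containing it, or :data:`UNASSIGNED`.

    A frame belongs to a core when its Euclidean distance to the center is
    ``<= radius`` (boundary inclusive). Core disjointness guarantees the
    assignment is unique, idempotent, and independent of core order.
    """
    if traj.n_cvs != defn.dim:
        raise ValueError(
            f"trajectory has {traj.n_cvs} CVs but cores are defined in "
            f"{defn.dim} dimensions"
        )
    labels = np.full(traj.n_frames, UNASSIGNED, dtype=np.int64)
    for k, core in enumerate(defn.cores):
        d2 = np.sum((traj.data - core.center) ** 2, axis=1)
        labels[d2 <= core.radius ** 2] = k
    return LabelSequence(labels, frame_interval=traj.frame_interval,
                         n_cores=defn.n_cores, state_names=defn.names)


def occupancy(labels: LabelSequence) -> np.ndarray:
    """Fraction of frames in each core, with the unassigned fraction last.

    Returns a vector of length ``n_cores + 1`` summing to 1.
    """
    lab = labels.labels
    n = labels.n_cores
    out = np.empty(n + 1)
    for k in range(n):
        out[k] = np.count_nonzero(lab == k)
    out[n] = np.count_nonzero(lab == UNASSIGNED)
    return out / lab.size
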