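"""Synthetic trajectory generators with the statistical structure the
kinetic analysis assumes.

Four generators stand in for data an MD simulation would supply:

* :func:`sample_chain` — discrete Markov chains with a known transition
  matrix, the exact generative counterpart of the estimated MSM.
* :func:`sample_lumped_chain` — observable chains built by lumping hidden
  Markov states; the observed process is non-Markovian whenever lumped
  states have distinct outgoing rows, which is exactly the regime the
  history-augmented analysis is designed for.
* :func:`simulate_brownian_2d` — overdamped Brownian dynamics on a smooth
  2-D free-energy landscape built from a Gaussian-mixture density, with
  wells at user-chosen centers (e.g. the folded/misfolded/intermediate
  cores at (−3, 0), (3, −5), (2, 2)).
* :func:`sample_circle` — a noisy unit circle, the standard validation
  manifold for diffusion maps (analytic eigenfunctions are sine/cosine).

All generators take explicit integer seeds and never touch global random
state; a fixed seed gives bit-identical output on a given backend (the
compiled and pure-NumPy paths consume the identical random stream but may
differ in the last ulp of transcendental-function arithmetic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._jit import njit
from .states import LabelSequence
from .trajectory import CVTrajectory

#: Additive floor under the Gaussian-mixture density: keeps the potential
#: −kT·log(mixture + floor) finite and the force bounded far from the wells.
DENSITY_FLOOR = 1e-8

_ROW_TOL = 1e-12


def _check_stochastic(T: np.ndarray, what: str = "T_true") -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError(f"{what} must be a square matrix")
    if (T < 0).any():
        raise ValueError(f"{what} has negative entries")
    rows = T.sum(axis=1)
    if np.max(np.abs(rows - 1.0)) > _ROW_TOL:
        raise ValueError(f"{what} rows must sum to 1 within {_ROW_TOL}")
    return T


@dataclass(frozen=True)
class ChainSpec:
    """Specification of a finite Markov chain to sample.

    ``T_true`` is row-stochastic (rows sum to 1 within 1e−12); the chain is
    started from ``initial_distribution`` and run for ``n_frames`` frames.
    """

    n_states: int
    T_true: np.ndarray
    initial_distribution: np.ndarray
    n_frames: int
    seed: int

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("n_states must be positive")
        T = _check_stochastic(self.T_true)
        if T.shape[0] != self.n_states:
            raise ValueError("T_true shape does not match n_states")
        p0 = np.asarray(self.initial_distribution, dtype=float)
        if p0.shape != (self.n_states,) or (p0 < 0).any() or abs(p0.sum() - 1.0) > _ROW_TOL:
            raise ValueError("initial_distribution must be a length-n probability vector")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        object.__setattr__(self, "T_true", T)
        object.__setattr__(self, "initial_distribution", p0)


@njit(cache=True)
def _chain_kernel(cum, s0, u):  # pragma: no cover - exercised via sample_chain
    n = u.shape[0]
    m = cum.shape[1]
    out = np.empty(n + 1, np.int64)
    out[0] = s0
    s = s0
    for t in range(n):
        j = np.searchsorted(cum[s], u[t], side="right")
        if j >= m:
            j = m - 1
        s = j
        out[t + 1] = s
    return out


def sample_chain(spec: ChainSpec, frame_interval: float = 1.0) -> LabelSequence:
    """Sample a state sequence from a known Markov chain.

    Frame ``t+1`` is drawn from row ``s(t)`` of ``T_true``; the first frame
    is drawn from the initial distribution.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.n_frames)  # u[0] picks the initial state
    cum_init = np.cumsum(spec.initial_distribution)
    s0 = int(min(np.searchsorted(cum_init, u[0], side="right"), spec.n_states - 1))
    cum = np.cumsum(spec.T_true, axis=1)
    labels = _chain_kernel(cum, s0, u[1:])
    return LabelSequence(labels, frame_interval=frame_interval, n_cores=spec.n_states)


@dataclass(frozen=True)
class Well:
    """One well of the landscape: Gaussian bump of the mixture density.

    ``depth`` (kT units) sets the bump amplitude exp(depth); ``width`` is the
    Gaussian standard deviation in CV units, which for an isolated well is
    also the standard deviation of the stationary in-well distribution.
    """

    center: np.ndarray
    depth: float
    width: float

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float)
        if c.shape != (2,):
            raise ValueError("well center must be a 2-vector")
        if not (self.depth > 0):
            raise ValueError("well depth must be positive")
        if not (self.width > 0):
            raise ValueError("well width must be positive")
        object.__setattr__(self, "center", c)


@dataclass(frozen=True)
class LandscapeSpec:
    """Overdamped Brownian dynamics on a 2-D Gaussian-mixture landscape.

    The potential is ``U(x) = −kT·log(Σ_k exp(depth_k)·G_k(x) + floor)``
    with unit-height Gaussians ``G_k`` of the given centers/widths, so every
    listed center is a genuine smooth minimum. Integration is
    Euler–Maruyama with time step ``dt_integrate``; every ``stride_save``-th
    step is saved, and the first saved frame is the initial position.

    Construction rejects specs whose per-step displacement standard
    deviation ``sqrt(2·D·dt)`` is not smaller than the narrowest well.
    """

    wells: tuple
    kT: float = 1.0
    diffusion_coefficient: float = 1.0
    dt_integrate: float = 0.01
    stride_save: int = 10
    n_frames: int = 10000
    seed: int = 0
    x0: np.ndarray = None

    def __post_init__(self):
        wells = tuple(self.wells)
        if not wells:
            raise ValueError("at least one well is required")
        if self.kT <= 0 or self.diffusion_coefficient < 0 or self.dt_integrate <= 0:
            raise ValueError("kT, diffusion_coefficient, dt_integrate must be positive "
                             "(diffusion_coefficient may be 0)")
        if self.stride_save < 1 or self.n_frames < 1:
            raise ValueError("stride_save and n_frames must be positive")
        step_sd = math.sqrt(2.0 * self.diffusion_coefficient * self.dt_integrate)
        wmin = min(w.width for w in wells)
        if step_sd >= wmin:
            raise ValueError(
                f"per-step displacement std {step_sd:.4g} must be smaller than the "
                f"narrowest well width {wmin:.4g}; reduce dt_integrate or D"
            )
        x0 = self.x0
        x0 = wells[0].center.copy() if x0 is None else np.asarray(x0, dtype=float)
        if x0.shape != (2,) or not np.all(np.isfinite(x0)):
            raise ValueError("x0 must be a finite 2-vector")
        object.__setattr__(self, "wells", wells)
        object.__setattr__(self, "x0", x0)

    @property
    def frame_interval(self) -> float:
        return self.dt_integrate * self.stride_save

    @classmethod
    def three_well(cls, n_frames: int = 100000, seed: int = 0, width: float = 1.0,
                   depth: float = 5.0, **kwargs) -> "LandscapeSpec":
        """Chignolin-like three-well landscape with cores at (−3, 0),
        (3, −5), (2, 2). Defaults give metastable wells with barriers of a
        few kT, so long runs visit all three cores."""
        centers = [(-3.0, 0.0), (3.0, -5.0), (2.0, 2.0)]
        wells = tuple(Well(np.array(c), depth, width) for c in centers)
        return cls(wells=wells, n_frames=n_frames, seed=seed, **kwargs)


@njit(cache=True)
def _brownian_kernel(x, centers, amps, inv2w2, mob_dt, floor, noise, stride,
                     out, isave0):  # pragma: no cover - exercised via simulate
    n_steps = noise.shape[0]
    n_wells = centers.shape[0]
    isave = isave0
    for t in range(n_steps):
        q = floor
        gx = 0.0
        gy = 0.0
        for k in range(n_wells):
            dx = centers[k, 0] - x[0]
            dy = centers[k, 1] - x[1]
            e = amps[k] * np.exp(-(dx * dx + dy * dy) * inv2w2[k])
            q += e
            w = 2.0 * inv2w2[k]  # 1/width^2
            gx += e * dx * w
            gy += e * dy * w
        x[0] += mob_dt * gx / q + noise[t, 0]
        x[1] += mob_dt * gy / q + noise[t, 1]
        if not (np.isfinite(x[0]) and np.isfinite(x[1])):
            return t, isave
        if (t + 1) % stride == 0:
            out[isave, 0] = x[0]
            out[isave, 1] = x[1]
            isave += 1
    return -1, isave


def simulate_brownian_2d(spec: LandscapeSpec) -> CVTrajectory:
    """Integrate overdamped Brownian dynamics on the landscape.

    The drift is ``(D/kT)·F·dt`` with force ``F = −∇U = kT·∇q/(q+floor)``,
    plus Gaussian noise of standard deviation ``sqrt(2·D·dt)`` per step and
    coordinate. Noise is generated in chunks from a single seeded stream, so
    the result is bit-identical for a fixed seed regardless of chunking.
    """
    rng = np.random.default_rng(spec.seed)
    centers = np.array([w.center for w in spec.wells])
    amps = np.array([math.exp(w.depth) for w in spec.wells])
    inv2w2 = np.array([1.0 / (2.0 * w.width ** 2) for w in spec.wells])
    mob_dt = spec.diffusion_coefficient * spec.dt_integrate
    noise_sd = math.sqrt(2.0 * spec.diffusion_coefficient * spec.dt_integrate)

    n_steps = (spec.n_frames - 1) * spec.stride_save
    out = np.empty((spec.n_frames, 2))
    x = spec.x0.copy()
    out[0] = x
    isave = 1
    chunk = max(spec.stride_save, (1_000_000 // spec.stride_save) * spec.stride_save)
    done = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = rng.standard_normal((m, 2)) * noise_sd
        fail, isave = _brownian_kernel(x, centers, amps, inv2w2, mob_dt,
                                       DENSITY_FLOOR, noise, spec.stride_save,
                                       out, isave)
        if fail >= 0:
            raise RuntimeError(
                f"Brownian integration diverged (non-finite coordinate) at "
                f"step {done + fail}"
            )
        done += m
    return CVTrajectory(out, frame_interval=spec.frame_interval,
                        columns=("x", "y"))


def landscape_potential(spec: LandscapeSpec, points: np.ndarray) -> np.ndarray:
    """Evaluate U(x) (same units as kT) at an (n, 2) array of points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    q = np.full(pts.shape[0], DENSITY_FLOOR)
    for w in spec.wells:
        d2 = np.sum((pts - w.center) ** 2, axis=1)
        q += math.exp(w.depth) * np.exp(-d2 / (2.0 * w.width ** 2))
    return -spec.kT * np.log(q)


@dataclass(frozen=True)
class LumpingSpec:
    """A hidden Markov chain plus a surjective hidden→observed state map."""

    hidden_chain: ChainSpec
    lump_map: np.ndarray  # length n_hidden, values = observed labels

    def __post_init__(self):
        m = np.asarray(self.lump_map, dtype=np.int64)
        if m.shape != (self.hidden_chain.n_states,):
            raise ValueError("lump_map must have one entry per hidden state")
        if (m < 0).any():
            raise ValueError("observed labels must be nonnegative")
        n_obs = int(m.max()) + 1
        if set(m.tolist()) != set(range(n_obs)):
            raise ValueError("lump_map must be surjective onto 0..n_obs-1")
        object.__setattr__(self, "lump_map", m)

    @property
    def n_observed(self) -> int:
        return int(self.lump_map.max()) + 1


def sample_lumped_chain(spec: LumpingSpec, frame_interval: float = 1.0) -> LabelSequence:
    """Sample the hidden chain and apply the lump map frame-wise.

    With ``lump_map`` the identity this reproduces :func:`sample_chain` of
    the hidden chain under the same seed. When lumped hidden states have
    distinct outgoing rows the observed process carries memory of which
    hidden state it is in — the regime where a plain MSM is biased and the
    history-augmented analysis is not.
    """
    hidden = sample_chain(spec.hidden_chain, frame_interval=frame_interval)
    return LabelSequence(spec.lump_map[hidden.labels], frame_interval=frame_interval,
                         n_cores=spec.n_observed)


def sample_circle(n: int, noise_sd: float = 0.0, seed: int = 0,
                  spacing: str = "even") -> CVTrajectory:
    """Points on the unit circle plus isotropic Gaussian noise.

    ``spacing='even'`` places angles at ``2πi/n``; ``'uniform'`` draws them
    uniformly at random. Used to validate diffusion maps: the Laplacian
    eigenfunctions on a circle are sine/cosine pairs, so the second and
    third DM coordinates should recover the angle.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if spacing == "even":
        theta = 2.0 * np.pi * np.arange(n) / n
    elif spacing == "uniform":
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    else:
        raise ValueError("spacing must be 'even' or 'uniform'")
    pts = np.column_stack([np.cos(theta), np.sin(theta)])
    if noise_sd > 0:
        pts = pts + rng.normal(scale=noise_sd, size=pts.shape)
    return CVTrajectory(pts, frame_interval=1.0, columns=("x", "y"))


def circle_points(n: int, noise_sd: float = 0.0, seed: int = 0,
                  spacing: str = "even") -> np.ndarray:
    """Convenience: :func:`sample_circle` returning the bare point array."""
    return sample_circle(n, noise_sd=noise_sd, seed=seed, spacing=spacing).data
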