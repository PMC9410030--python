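"""Delimited-text readers/writers and run configuration.

Canonical formats: TSV with a header row for tabular data (trajectories,
label sequences, matrices, histograms) and JSON for nested results.
Trajectory files may carry a ``# frame_interval = <value>`` comment
directive; a column named ``t``/``time`` is recognized as the time axis and
used to infer the frame interval when no directive or argument supplies it.
Frame indices are 0-based everywhere.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .states import Core, LabelSequence, StateDefinition
from .trajectory import CVTrajectory

_DIRECTIVE = re.compile(r"#\s*frame_interval\s*[=:]\s*([0-9eE.+-]+)")
_TIME_NAMES = {"t", "time"}


def _scan_directive(path) -> float:
    with open(path, "r", newline="") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if not line.startswith("#"):
                break
            m = _DIRECTIVE.match(line)
            if m:
                return float(m.group(1))
    return None


def _detect_delimiter(path) -> str:
    """Pick tab, comma, or whitespace from the first non-comment line."""
    with open(path, "r", newline="") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "\t" in line:
                return "\t"
            if "," in line:
                return ","
            return r"\s+"
    raise ValueError(f"{path}: no data lines")


def read_cv_trajectory(path, delimiter=None, frame_interval=None) -> CVTrajectory:
    """Read a delimited-text CV trajectory.

    Delimiter is detected from the header when not given (tab, comma, or
    whitespace); ``#`` lines are comments. Frame interval priority: explicit
    argument, header directive, uniform spacing of a ``t``/``time`` column,
    then 1.0.
    """
    path = Path(path)
    directive = _scan_directive(path)
    sep = delimiter if delimiter is not None else _detect_delimiter(path)
    try:
        # parse cells as text, then convert through numpy's correctly-rounded
        # float parser so full-precision writes round-trip bit-identically
        df = pd.read_csv(path, sep=sep, engine="python", comment="#",
                         skip_blank_lines=True, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"{path}: empty trajectory")
    for col in df.columns:
        raw = df[col]
        missing = np.flatnonzero(raw.isna().to_numpy())
        if missing.size:
            raise ValueError(f"{path}: ragged/missing cell at data row "
                             f"{missing[0]}, column {col!r}")
        try:
            df[col] = raw.to_numpy().astype(float)
        except ValueError:
            for i, cell in enumerate(raw):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(f"{path}: non-numeric cell at data row "
                                     f"{i}, column {col!r}") from None
            raise
    time_col = next((c for c in df.columns if str(c).strip().lower() in _TIME_NAMES),
                    None)
    inferred = None
    if time_col is not None:
        t = df.pop(time_col).to_numpy()
        if t.size > 1:
            dt = np.diff(t)
            if dt.size and np.allclose(dt, dt[0], rtol=1e-8, atol=0) and dt[0] > 0:
                inferred = float(dt[0])
    fi = frame_interval if frame_interval is not None else \
        directive if directive is not None else \
        inferred if inferred is not None else 1.0
    return CVTrajectory(df.to_numpy(dtype=float), frame_interval=fi,
                        columns=tuple(str(c) for c in df.columns))


def write_cv_trajectory(traj: CVTrajectory, path, delimiter="\t") -> None:
    """Write a trajectory at full precision (round-trips bit-identically)."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# frame_interval = {traj.frame_interval!r}\n")
        fh.write(delimiter.join(traj.columns) + "\n")
        for row in traj.data:
            fh.write(delimiter.join(f"{v:.17g}" for v in row) + "\n")


def read_labels(path, frame_interval=None) -> LabelSequence:
    directive = _scan_directive(path)
    df = pd.read_csv(path, sep=_detect_delimiter(path), engine="python",
                     comment="#")
    col = "state" if "state" in df.columns else df.columns[-1]
    fi = frame_interval if frame_interval is not None else \
        directive if directive is not None else 1.0
    return LabelSequence(df[col].to_numpy(dtype=np.int64), frame_interval=fi)


def write_labels(labels: LabelSequence, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# frame_interval = {labels.frame_interval!r}\n")
        fh.write("frame\tstate\n")
        for i, s in enumerate(labels.labels):
            fh.write(f"{i}\t{s}\n")


def write_matrix(mat, path, names=None) -> None:
    """Square matrix as TSV with a header row/column naming the states."""
    mat = np.asarray(mat)
    names = [str(i) for i in range(mat.shape[0])] if names is None else list(names)
    pd.DataFrame(mat, index=names, columns=names).to_csv(path, sep="\t",
                                                         float_format="%.12g")


def write_fptd(fptd, path) -> None:
    """FPT distribution as TSV: step, time, probability."""
    df = pd.DataFrame({"step": fptd.steps, "time": fptd.times,
                       "probability": fptd.probabilities})
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# lag = {fptd.lag}, frame_interval = {fptd.frame_interval!r}, "
                 f"tail_mass = {fptd.tail_mass:.6g}, mean = {fptd.mean:.12g}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")


def state_definition_from_dict(d) -> StateDefinition:
    cores = tuple(Core(str(c["name"]), np.asarray(c["center"], dtype=float),
                       float(c["radius"])) for c in d["cores"])
    return StateDefinition(cores=cores)


def state_definition_to_dict(defn: StateDefinition) -> dict:
    return {"cores": [{"name": c.name, "center": c.center.tolist(),
                       "radius": c.radius} for c in defn.cores]}


def read_state_definition(path) -> StateDefinition:
    path = Path(path)
    with open(path) as fh:
        d = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    return state_definition_from_dict(d)


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    output_dir: Path
    seed: int = 0
    frame_interval: float = 1.0
    lag: int = 1
    trajectory: Path = None          # input path; None -> simulate
    simulate: dict = field(default_factory=dict)
    states: dict = None              # state-definition dict; None -> three-state default
    pairs: list = field(default_factory=list)
    kernel: dict = field(default_factory=dict)
    window_length: int = None
    n_eigs: int = 4
    dm_stride: int = 1
    fes_bins: int = 60
    n_max: int = 10000

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        if self.frame_interval <= 0 or self.lag < 1:
            raise ValueError("frame_interval must be positive and lag >= 1")
        if self.trajectory is not None:
            self.trajectory = Path(self.trajectory)
            if not self.trajectory.exists():
                raise ValueError(f"trajectory path does not exist: {self.trajectory}")
        if self.trajectory is None and not self.simulate:
            raise ValueError("config must give either a trajectory path or a "
                             "simulate block")

    @property
    def state_definition(self) -> StateDefinition:
        if self.states is None:
            return StateDefinition.folding_three_state()
        return state_definition_from_dict(self.states)


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
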