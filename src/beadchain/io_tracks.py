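"""Track-table and trajectory I/O, plus the synthetic track generator.

Tracked tracer positions arrive as CSV in either a Trackmate-style dialect
(``TRACK_ID, FRAME, POSITION_X, POSITION_Y`` columns, calibrated units) or a
minimal ``track, frame, x, y`` dialect.  Coordinates default to millimetres
(the usual tracking calibration); the ``length_unit`` scale converts to SI
at analysis time.  Frames are 0-based and times are frame/frame_rate, with
the 30 Hz X-ray video rate as the default.

Simulated trajectories can be written as XYZ (element tags B/C/A for
bead/crimp/anchor), as a LAMMPS-dump-style text format
(``ITEM: TIMESTEP`` blocks with id/type/x/y/z/vx/vy/vz) or as an HDF5
container that round-trips bit-for-bit.

The synthetic track generator emulates the tracked output of the experiment
- 2D projected positions of a handful of tracers at the camera frame rate -
with a configurable per-component velocity distribution, detection noise
and frame dropout, so the whole analysis path is testable without any
experimental data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .forcefield import _laplace_from_uniforms
from .simulator import Trajectory

__all__ = [
    "TrackTable",
    "read_tracks_csv",
    "generate_synthetic_tracks",
    "write_trajectory",
    "read_trajectory",
]

_TRACKMATE_COLUMNS = {"TRACK_ID": "track", "FRAME": "frame",
                      "POSITION_X": "x", "POSITION_Y": "y"}
_SIMPLE_COLUMNS = ("track", "frame", "x", "y")
_KIND_TAG = {"bead": "B", "crimp": "C", "anchor": "A"}
_TAG_KIND = {v: k for k, v in _KIND_TAG.items()}
_KIND_TYPE = {"crimp": 1, "bead": 2, "anchor": 3}
_TYPE_KIND = {v: k for k, v in _KIND_TYPE.items()}


@dataclass
class TrackTable:
    """Tracked 2D positions: one row per (track, frame).

    ``data`` holds columns ``track`` (int), ``frame`` (int >= 0), ``x``,
    ``y`` (in units of ``length_unit`` metres) and optionally ``quality``.
    """

    data: pd.DataFrame
    frame_rate: float = 30.0
    length_unit: float = 1e-3
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in _SIMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"track table missing columns: {missing}")
        if self.frame_rate <= 0 or self.length_unit <= 0:
            raise ValidationError("frame_rate and length_unit must be positive")
        if len(df):
            if (df["frame"] < 0).any():
                raise ValidationError("negative frame indices")
            if not np.all(np.isfinite(df[["x", "y"]].to_numpy(dtype=float))):
                raise ValidationError("non-finite coordinates")
            if df.duplicated(subset=["track", "frame"]).any():
                raise SchemaError("duplicate (track, frame) rows")
        self.data = df.sort_values(["track", "frame"], ignore_index=True)

    @property
    def n_tracks(self) -> int:
        return int(self.data["track"].nunique())

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path, dialect: str = "simple") -> None:
        df = self.data
        if dialect == "simple":
            df.to_csv(path, index=False)
        elif dialect == "trackmate":
            out = df.rename(columns={v: k for k, v in _TRACKMATE_COLUMNS.items()})
            out.to_csv(path, index=False)
        else:
            raise ValidationError(f"unknown dialect {dialect!r}")


def read_tracks_csv(path, dialect: str = "auto", frame_rate: float = 30.0,
                    length_unit: float = 1e-3) -> TrackTable:
    """Read a track CSV in the Trackmate or simple dialect.

    ``dialect='auto'`` sniffs the header.  Rows come back sorted by
    (track, frame); duplicated (track, frame) pairs raise
    :class:`SchemaError`, as do missing columns (named in the message).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if dialect == "auto":
        dialect = "trackmate" if "TRACK_ID" in cols else "simple"
    if dialect == "trackmate":
        missing = [c for c in _TRACKMATE_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"missing required Trackmate columns: {missing}")
        df = df.rename(columns=_TRACKMATE_COLUMNS)
    elif dialect == "simple":
        missing = [c for c in _SIMPLE_COLUMNS if c not in cols]
        if missing:
            raise SchemaError(f"missing required columns: {missing}")
    else:
        raise ValidationError(f"unknown dialect {dialect!r}")
    keep = [c for c in ("track", "frame", "x", "y", "quality") if c in df.columns]
    df = df[keep].astype({"track": np.int64, "frame": np.int64})
    return TrackTable(df, frame_rate=frame_rate, length_unit=length_unit)


def generate_synthetic_tracks(
    n_tracers: int = 5,
    n_frames: int = 1000,
    frame_rate: float = 30.0,
    velocity_model: tuple[str, float] = ("laplace", 0.05),
    detection_noise_sd: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
    length_unit: float = 1e-3,
) -> TrackTable:
    """Generate seeded synthetic tracer tracks with a known velocity law.

    Each tracer performs a 2D random walk whose per-frame displacement is an
    independent per-component velocity draw (Laplace or Gaussian with the
    given scale, m/s) divided by the frame rate - i.e. the finite-difference
    velocities of a perfect track recover exactly the chosen distribution.
    Gaussian detection noise (``detection_noise_sd``, metres) is added to
    each detected position, and frames are dropped independently with
    probability ``dropout``, emulating motion-blur detection failures.
    """
    kind, scale = velocity_model
    if kind not in ("laplace", "gaussian"):
        raise ValidationError(f"velocity_model kind must be laplace|gaussian, got {kind!r}")
    if not (0.0 <= dropout <= 1.0):
        raise ValidationError("dropout must lie in [0, 1]")
    if n_tracers < 1 or n_frames < 1:
        raise ValidationError("n_tracers and n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for t_id in range(n_tracers):
        start = rng.uniform(-0.05, 0.05, size=2)
        if kind == "gaussian":
            v = scale * rng.standard_normal((n_frames - 1, 2))
        else:
            u = rng.random((n_frames - 1, 2, 2))
            v = scale * _laplace_from_uniforms(u[..., 0], u[..., 1])
        pos = np.vstack([start, start + np.cumsum(v / frame_rate, axis=0)])
        if detection_noise_sd > 0:
            pos = pos + detection_noise_sd * rng.standard_normal(pos.shape)
        detected = rng.random(n_frames) >= dropout
        for f in np.flatnonzero(detected):
            rows.append((t_id, int(f), pos[f, 0] / length_unit,
                         pos[f, 1] / length_unit))
    df = pd.DataFrame(rows, columns=["track", "frame", "x", "y"])
    return TrackTable(df, frame_rate=frame_rate, length_unit=length_unit,
                      meta={"velocity_model": list(velocity_model),
                            "detection_noise_sd": detection_noise_sd,
                            "dropout": dropout, "seed": seed})


# ---------------------------------------------------------------------------
# Trajectory writers/readers
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path, format: Optional[str] = None) -> None:
    """Write a trajectory as 'xyz', 'lammps_dump' or 'hdf5'.

    The format is inferred from the suffix (.xyz, .dump/.lammpstrj, .h5/.hdf5)
    when not given.  HDF5 is lossless; the text formats print 9 significant
    digits.
    """
    path = Path(path)
    fmt = format or {".xyz": "xyz", ".dump": "lammps_dump",
                     ".lammpstrj": "lammps_dump", ".h5": "hdf5",
                     ".hdf5": "hdf5"}.get(path.suffix.lower())
    if fmt == "xyz":
        _write_xyz(traj, path)
    elif fmt == "lammps_dump":
        _write_dump(traj, path)
    elif fmt == "hdf5":
        _write_h5(traj, path)
    else:
        raise ValidationError(f"unknown trajectory format {format or path.suffix!r}")


def read_trajectory(path, format: Optional[str] = None) -> Trajectory:
    """Read back a trajectory written by :func:`write_trajectory`.

    The text formats carry limited metadata: XYZ recovers kinds, times and
    positions (velocities zero); the dump format also recovers velocities.
    """
    path = Path(path)
    fmt = format or {".xyz": "xyz", ".dump": "lammps_dump",
                     ".lammpstrj": "lammps_dump", ".h5": "hdf5",
                     ".hdf5": "hdf5"}.get(path.suffix.lower())
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "lammps_dump":
        return _read_dump(path)
    if fmt == "hdf5":
        return _read_h5(path)
    raise ValidationError(f"unknown trajectory format {format or path.suffix!r}")


def _write_xyz(traj: Trajectory, path: Path) -> None:
    n = traj.n_particles
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{n}\n")
            fh.write(f"t= {traj.times[f]:.9g}\n")
            for i in range(n):
                x, y, z = traj.positions[f, i]
                fh.write(f"{_KIND_TAG[traj.kinds[i]]} {x:.9g} {y:.9g} {z:.9g}\n")


def _read_xyz(path: Path) -> Trajectory:
    times, frames, kinds = [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i])
        times.append(float(lines[i + 1].split()[-1]))
        block = lines[i + 2:i + 2 + n]
        kinds = [_TAG_KIND[ln.split()[0]] for ln in block]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    pos = np.array(frames) if frames else np.empty((0, 0, 3))
    return Trajectory(times=np.array(times), positions=pos,
                      velocities=np.zeros_like(pos), kinds=kinds or [],
                      radii=np.zeros(pos.shape[1] if pos.size else 0),
                      masses=np.zeros(pos.shape[1] if pos.size else 0))


def _write_dump(traj: Trajectory, path: Path) -> None:
    n = traj.n_particles
    dt = traj.config.get("timestep", 1.0)
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            lo, hi = -1.0, 1.0
            if n:
                lo = float(traj.positions[f].min() - 0.01)
                hi = float(traj.positions[f].max() + 0.01)
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{int(round(traj.times[f] / dt))}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{n}\n")
            fh.write("ITEM: BOX BOUNDS ff ff ff\n")
            for _ in range(3):
                fh.write(f"{lo:.9g} {hi:.9g}\n")
            fh.write("ITEM: ATOMS id type x y z vx vy vz\n")
            for i in range(n):
                x, y, z = traj.positions[f, i]
                vx, vy, vz = traj.velocities[f, i]
                fh.write(f"{i + 1} {_KIND_TYPE[traj.kinds[i]]} "
                         f"{x:.9g} {y:.9g} {z:.9g} {vx:.9g} {vy:.9g} {vz:.9g}\n")


def _read_dump(path: Path) -> Trajectory:
    steps, pos_frames, vel_frames, kinds = [], [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        assert lines[i].startswith("ITEM: TIMESTEP")
        steps.append(int(lines[i + 1]))
        n = int(lines[i + 3])
        i += 9  # through the ATOMS header
        block = lines[i:i + n]
        rows = [ln.split() for ln in block]
        rows.sort(key=lambda r: int(r[0]))
        kinds = [_TYPE_KIND[int(r[1])] for r in rows]
        pos_frames.append([[float(v) for v in r[2:5]] for r in rows])
        vel_frames.append([[float(v) for v in r[5:8]] for r in rows])
        i += n
    pos = np.array(pos_frames) if pos_frames else np.empty((0, 0, 3))
    vel = np.array(vel_frames) if vel_frames else np.empty((0, 0, 3))
    return Trajectory(times=np.array(steps, dtype=float), positions=pos,
                      velocities=vel, kinds=kinds or [],
                      radii=np.zeros(pos.shape[1] if pos.size else 0),
                      masses=np.zeros(pos.shape[1] if pos.size else 0))


def _write_h5(traj: Trajectory, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("times", data=traj.times)
        h5.create_dataset("positions", data=traj.positions)
        h5.create_dataset("velocities", data=traj.velocities)
        h5.create_dataset("radii", data=traj.radii)
        h5.create_dataset("masses", data=traj.masses)
        h5.create_dataset("kinds", data=np.array(traj.kinds, dtype="S8"))
        h5.attrs["config"] = json.dumps(traj.config)
        h5.attrs["meta"] = json.dumps(traj.meta)


def _read_h5(path: Path) -> Trajectory:
    with h5py.File(path, "r") as h5:
        return Trajectory(
            times=h5["times"][()],
            positions=h5["positions"][()],
            velocities=h5["velocities"][()],
            kinds=[k.decode() for k in h5["kinds"][()]],
            radii=h5["radii"][()],
            masses=h5["masses"][()],
            config=json.loads(h5.attrs.get("config", "{}")),
            meta=json.loads(h5.attrs.get("meta", "{}")),
        )
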