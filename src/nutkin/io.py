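"""File dialects and run configuration.

Plain-CSV dialects (all seeded metadata carried in ``#`` comment lines,
tolerated and preserved by the readers):

* track CSV: ``t,x,y`` (s, mm, mm) — written by the simulator, read by
  the inversion;
* organ-state CSV (long format): ``t,s,rest_length,C,psi_c`` — one row
  per material segment per saved frame;
* centerline CSV: ``s,x,y,z,tx,ty,tz,d1x,d1y,d1z``.

``RunConfig`` is the JSON-serializable simulation configuration; its
canonical-JSON SHA1 (``config_hash``) stamps every output so identical
configs are verifiably identical runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MaterialSegment, OrganState
from .geometry import ApicalTrack, Centerline3D

__all__ = [
    "RunConfig",
    "write_track",
    "read_track",
    "write_organ_frames",
    "read_organ_frames",
    "frames_to_fields",
    "write_centerline",
    "read_centerline",
]

FLOAT_FMT = "%.12g"  # lossless to 12 significant digits


@dataclass(frozen=True)
class RunConfig:
    """Simulation configuration (driver, geometry, integration, noise).

    ``preset`` selects a registry driver (int key or name); explicit
    driver parameters go in ``driver_overrides``.  ``dt * omega`` is
    guarded below 1e-2 to keep explicit stepping well inside its
    stability/accuracy regime.
    """

    preset: int | str = 3
    driver_overrides: dict = field(default_factory=dict)
    radius: float = 0.5  # mm
    length: float = 20.0  # mm
    n_segments: int = 100
    dt: float | None = None  # s; None = auto from the fastest driver rate
    t_end: float | None = None  # s; default 5 driver periods
    save_stride: int = 5
    curv0: float = 0.0  # initial uniform curvature, 1/mm
    psi_c0: float = 0.0
    start_on_orbit: bool = True  # start on the rotating drive's periodic orbit
    scheme: str = "euler"
    keep_quadratic: bool = False
    noise_sd: float = 0.0  # track position noise, fraction of scale
    seed: int = 0

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")
        if self.n_segments < 1:
            raise ValueError("need at least one segment")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @property
    def config_hash(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]


def _write_csv(path, df: pd.DataFrame, comments: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for k, v in comments.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _read_comments(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_track(path, track: ApicalTrack, config_hash: str = "", **meta) -> None:
    df = pd.DataFrame({"t": track.times, "x": track.x, "y": track.y})
    comments = {"config_hash": config_hash, **meta} if config_hash or meta else {}
    _write_csv(path, df, comments)


def read_track(path, time_unit: str = "s") -> ApicalTrack:
    """Read a ``t,x,y`` CSV; ``time_unit`` 's', 'min' or 'h' converts to s."""
    df = pd.read_csv(path, comment="#")
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    factor = {"s": 1.0, "min": 60.0, "h": 3600.0}[time_unit]
    return ApicalTrack(df["t"].to_numpy() * factor, df["x"].to_numpy(),
                       df["y"].to_numpy())


def write_organ_frames(path, frames, config_hash: str = "", **meta) -> None:
    """Long-format organ-state CSV, one row per segment per saved frame."""
    rows = []
    for st in frames:
        s = st.abscissae
        rows.append(
            pd.DataFrame(
                {
                    "t": st.time,
                    "s": s,
                    "rest_length": st.rest_lengths,
                    "C": st.curvatures,
                    "psi_c": st.psi_cs,
                }
            )
        )
    comments = {"config_hash": config_hash, **meta} if config_hash or meta else {}
    _write_csv(path, pd.concat(rows, ignore_index=True), comments)


def read_organ_frames(path, radius: float | None = None):
    """Read an organ-state CSV back into a list of :class:`OrganState`.

    ``radius`` may be supplied explicitly or via a ``# radius=`` comment.
    """
    meta = _read_comments(path)
    if radius is None:
        if "radius" not in meta:
            raise ValueError("radius not given and not in the file header")
        radius = float(meta["radius"])
    df = pd.read_csv(path, comment="#")
    frames = []
    for t, grp in df.groupby("t", sort=True):
        grp = grp.sort_values("s")
        segs = [
            MaterialSegment(l, c, p)
            for l, c, p in zip(grp["rest_length"], grp["C"], grp["psi_c"])
        ]
        frames.append(OrganState(radius, segs, float(t)))
    return frames


def frames_to_fields(frames):
    """Stack saved frames into Lagrangian (n_times, n_segments) fields.

    Returns ``(times, C_field, psi_c_field)`` for
    :func:`nutkin.inversion.invert_from_3d`.
    """
    times = np.array([st.time for st in frames])
    C = np.vstack([st.curvatures for st in frames])
    psi = np.vstack([st.psi_cs for st in frames])
    return times, C, psi


def write_centerline(path, line: Centerline3D, config_hash: str = "", **meta):
    bounds = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(line.points, axis=0), axis=1))]
    )
    df = pd.DataFrame(
        {
            "s": bounds,
            "x": line.points[:, 0],
            "y": line.points[:, 1],
            "z": line.points[:, 2],
            "tx": line.tangents[:, 0],
            "ty": line.tangents[:, 1],
            "tz": line.tangents[:, 2],
            "d1x": line.directors[:, 0],
            "d1y": line.directors[:, 1],
            "d1z": line.directors[:, 2],
        }
    )
    comments = {"config_hash": config_hash, **meta} if config_hash or meta else {}
    _write_csv(path, df, comments)


def read_centerline(path) -> Centerline3D:
    df = pd.read_csv(path, comment="#")
    pts = df[["x", "y", "z"]].to_numpy()
    tans = df[["tx", "ty", "tz"]].to_numpy()
    dirs = df[["d1x", "d1y", "d1z"]].to_numpy()
    return Centerline3D(pts, tans, dirs)
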