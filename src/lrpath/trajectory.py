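"""Frames, trajectories and extended-XYZ I/O.

Coordinates use a right-handed frame with z along the membrane normal /
channel axis.  Units are angstroms for real structures and "model units"
for the coarse-grained toys; the unit label rides on the Trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .topology import SiteModel


class TrajectoryFormatError(ValueError):
    """Raised for malformed trajectory files."""


@dataclass
class Frame:
    """A single snapshot: N x 3 coordinates, a time stamp, an optional box."""

    coords: np.ndarray
    time: float = 0.0
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be N x 3, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.time < 0:
            raise ValueError("frame time must be non-negative")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError("box must be a 3-vector")

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def copy(self) -> "Frame":
        return Frame(
            self.coords.copy(),
            self.time,
            None if self.box is None else self.box.copy(),
        )


@dataclass
class Trajectory:
    """Ordered frames over a fixed topology.

    Invariants: strictly increasing frame times, constant site count, and
    the site count matches the topology when one is attached.
    """

    topology: SiteModel | None
    frames: list[Frame] = field(default_factory=list)
    units: str = "model"

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if not self.frames:
            return
        n = self.frames[0].n_sites
        if self.topology is not None and n != self.topology.n_sites:
            raise ValueError(
                f"frame has {n} sites but topology has {self.topology.n_sites}"
            )
        prev = -np.inf
        for f in self.frames:
            if f.n_sites != n:
                raise ValueError("inconsistent site count across frames")
            if f.time <= prev:
                raise ValueError("frame times must be strictly increasing")
            prev = f.time

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return Trajectory(self.topology, list(self.frames[i]), self.units)
        return self.frames[i]

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def coordinates(self) -> np.ndarray:
        """Stack all frame coordinates into an (n_frames, N, 3) array."""
        return np.array([f.coords for f in self.frames], dtype=float)

    def append(self, frame: Frame) -> None:
        if self.frames and frame.time <= self.frames[-1].time:
            raise ValueError("frame times must be strictly increasing")
        if self.topology is not None and frame.n_sites != self.topology.n_sites:
            raise ValueError("frame size does not match topology")
        if self.frames and frame.n_sites != self.frames[0].n_sites:
            raise ValueError("inconsistent site count across frames")
        self.frames.append(frame)

    def extend(self, frames: Iterable[Frame]) -> None:
        for f in frames:
            self.append(f)


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

_XYZ_FMT = "{name:<8s} {x:16.6f} {y:16.6f} {z:16.6f}\n"


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-frame extended XYZ.

    The comment line carries ``time=<t>`` and, when a box is present,
    ``box="bx by bz"``.  Coordinates are written to 6 decimals.
    """
    path = Path(path)
    names = (
        traj.topology.names
        if traj.topology is not None
        else [f"S{i}" for i in range(traj.frames[0].n_sites if traj.frames else 0)]
    )
    with path.open("w") as fh:
        for frame in traj.frames:
            fh.write(f"{frame.n_sites}\n")
            comment = f"time={frame.time:.9g} units={traj.units}"
            if frame.box is not None:
                bx, by, bz = frame.box
                comment += f' box="{bx:.6f} {by:.6f} {bz:.6f}"'
            fh.write(comment + "\n")
            for name, (x, y, z) in zip(names, frame.coords):
                fh.write(_XYZ_FMT.format(name=name, x=x, y=y, z=z))


def _parse_comment(line: str) -> tuple[float, np.ndarray | None, str]:
    time = 0.0
    box = None
    units = "model"
    i = 0
    # split on whitespace but respect double quotes
    tokens: list[str] = []
    cur = ""
    in_quote = False
    for ch in line:
        if ch == '"':
            in_quote = not in_quote
            cur += ch
        elif ch.isspace() and not in_quote:
            if cur:
                tokens.append(cur)
                cur = ""
        else:
            cur += ch
    if cur:
        tokens.append(cur)
    for tok in tokens:
        if "=" not in tok:
            continue
        key, _, val = tok.partition("=")
        val = val.strip('"')
        if key == "time":
            time = float(val)
        elif key == "box":
            box = np.array([float(v) for v in val.split()], dtype=float)
        elif key == "units":
            units = val
    return time, box, units


def read_xyz_trajectory(
    path: str | Path, topology: SiteModel | None = None
) -> Trajectory:
    """Read a multi-frame extended-XYZ file written by write_xyz_trajectory."""
    path = Path(path)
    frames: list[Frame] = []
    units = "model"
    n_expected: int | None = None
    with path.open() as fh:
        lines = fh.readlines()
    if not any(line.strip() for line in lines):
        raise TrajectoryFormatError(f"{path}: empty XYZ file")
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}:{i + 1}: expected atom count, got {lines[i].strip()!r}"
            ) from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryFormatError(
                f"{path}:{i + 1}: frame has {n} sites, expected {n_expected}"
            )
        if i + 1 >= len(lines):
            raise TrajectoryFormatError(f"{path}: truncated frame header")
        time, box, units = _parse_comment(lines[i + 1])
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise TrajectoryFormatError(f"{path}: truncated frame at line {i + 1}")
        coords = np.empty((n, 3), dtype=float)
        for j, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"{path}:{i + 3 + j}: expected 'name x y z'"
                )
            coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(coords, time=time, box=box))
        i += 2 + n
    return Trajectory(topology, frames, units=units)
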