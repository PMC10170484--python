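"""Trajectory, pressure-series, wall-force-log and isotherm I/O.

Supported textual formats:

* extended XYZ — per frame: a count line, a comment line carrying
  ``Lattice="ax 0 0 0 by 0 0 0 cz"`` (orthogonal boxes only) and optionally
  ``Time=<t>``, then one ``species x y z`` record per particle;
* a minimal LAMMPS-dump subset — ``ITEM: TIMESTEP`` / ``NUMBER OF ATOMS`` /
  ``BOX BOUNDS`` / ``ATOMS id type x y z`` blocks, orthogonal boxes,
  unscaled coordinates;
* CSV for pressure-tensor series and wall-force logs (pandas);
* JSON for assembled isotherms;
* YAML for run configuration.

Coordinates are taken exactly as stored: no re-imaging or re-origining is
performed, because the osmotic wall analysis relies on the ``|x| > x_wall``
convention with walls placed symmetrically about the origin.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .units import check_units

__all__ = [
    "Frame",
    "Trajectory",
    "PressureTensorSeries",
    "RunConfig",
    "ParseError",
    "StructureError",
    "SchemaError",
    "read_trajectory",
    "write_trajectory",
    "read_pressure_series",
    "write_pressure_series",
    "read_wall_force_log",
    "write_wall_force_log",
    "read_isotherm",
    "write_isotherm",
    "load_config",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """Malformed record in a trajectory file; carries the 1-based line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


class StructureError(ValueError):
    """Structurally inconsistent trajectory (e.g. varying particle count)."""


class SchemaError(ValueError):
    """CSV/JSON input missing a required column or field."""


@dataclass
class Frame:
    """One trajectory frame: coordinates, species tags and the box."""

    coords: np.ndarray  # (N, 3) float64
    species: np.ndarray  # (N,) str
    box: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.species = np.asarray(self.species, dtype=str)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if len(self.species) != len(self.coords):
            raise ValueError("coordinate count must equal species count")
        if any(b <= 0 for b in self.box):
            raise ValueError("all box lengths must be positive")

    @property
    def n_particles(self) -> int:
        return len(self.coords)


@dataclass
class Trajectory:
    """An ordered sequence of frames with a constant particle count."""

    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_particles
        for k, fr in enumerate(self.frames):
            if fr.n_particles != n0:
                raise StructureError(
                    f"frame {k} has {fr.n_particles} particles, expected {n0}"
                )
        times = [fr.time for fr in self.frames]
        if len(times) > 1 and any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise StructureError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def n_particles(self) -> int:
        return self.frames[0].n_particles

    @property
    def box(self) -> tuple[float, float, float]:
        return self.frames[0].box

    def species_set(self) -> set[str]:
        return set(self.frames[0].species.tolist())


@dataclass
class PressureTensorSeries:
    """Diagonal pressure-tensor components vs time, plus the box height L_z."""

    times: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    box_lz: float
    units: str = "reduced"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.pxx = np.asarray(self.pxx, dtype=np.float64)
        self.pyy = np.asarray(self.pyy, dtype=np.float64)
        self.pzz = np.asarray(self.pzz, dtype=np.float64)
        n = len(self.times)
        if not (len(self.pxx) == len(self.pyy) == len(self.pzz) == n):
            raise ValueError("time and pressure series must have equal length")
        if self.box_lz <= 0:
            raise ValueError("box_lz must be positive")
        check_units(self.units)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RunConfig:
    """Analysis configuration shared across modules."""

    units: str = "reduced"
    x_wall: float = 12.0
    wall_k: float = 50.0
    force_law: str = "quadratic-penetration"
    restrained_species: tuple[str, ...] = ("H", "T")
    solvent_species: str = "W"
    bin_width: float = 0.1
    sample_every: int = 20
    n_blocks: int = 5
    margin: float = 4.5

    def __post_init__(self) -> None:
        check_units(self.units)
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.n_blocks < 2:
            raise ValueError("block count must be >= 2")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")


def load_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    if "restrained_species" in data:
        data["restrained_species"] = tuple(data["restrained_species"])
    return RunConfig(**data)


# --------------------------------------------------------------------------
# extended XYZ


def _parse_lattice(comment: str, lineno: int) -> tuple[float, float, float]:
    key = 'Lattice="'
    start = comment.find(key)
    if start < 0:
        raise ParseError('comment line lacks Lattice="..." box entry', lineno)
    end = comment.find('"', start + len(key))
    if end < 0:
        raise ParseError("unterminated Lattice entry", lineno)
    try:
        cell = [float(tok) for tok in comment[start + len(key) : end].split()]
    except ValueError as exc:
        raise ParseError(f"non-numeric Lattice entry: {exc}", lineno) from None
    if len(cell) != 9:
        raise ParseError("Lattice must contain 9 numbers", lineno)
    m = np.array(cell).reshape(3, 3)
    if np.any(m != np.diag(np.diagonal(m))):
        raise ParseError("only orthogonal boxes are supported", lineno)
    return (m[0, 0], m[1, 1], m[2, 2])


def _parse_time(comment: str, default: float) -> float:
    for tok in comment.split():
        if tok.startswith("Time="):
            return float(tok[5:])
    return default


def _read_xyz(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"expected particle count, got {lines[i]!r}", i + 1)
        if i + 1 >= len(lines):
            raise ParseError("missing comment line after count", i + 2)
        box = _parse_lattice(lines[i + 1], i + 2)
        time = _parse_time(lines[i + 1], float(len(frames)))
        records = lines[i + 2 : i + 2 + n]
        if len(records) < n:
            raise ParseError(
                f"frame declares {n} particles but file ends after {len(records)}",
                len(lines),
            )
        species = []
        coords = np.empty((n, 3))
        for j, rec in enumerate(records):
            parts = rec.split()
            if len(parts) < 4:
                raise ParseError(f"expected 'species x y z', got {rec!r}", i + 3 + j)
            species.append(parts[0])
            try:
                coords[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ParseError(str(exc), i + 3 + j) from None
        frames.append(Frame(coords, np.array(species), box, time))
        i += 2 + n
    if not frames:
        raise ParseError("file contains no frames", 1)
    return frames


def _write_xyz(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        for fr in traj:
            lx, ly, lz = fr.box
            lattice = " ".join(
                _FLOAT_FMT % v for v in (lx, 0, 0, 0, ly, 0, 0, 0, lz)
            )
            fh.write(f"{fr.n_particles}\n")
            fh.write(f'Lattice="{lattice}" Time={_FLOAT_FMT % fr.time}\n')
            for sp, (x, y, z) in zip(fr.species, fr.coords):
                fh.write(
                    f"{sp} {_FLOAT_FMT % x} {_FLOAT_FMT % y} {_FLOAT_FMT % z}\n"
                )


# --------------------------------------------------------------------------
# minimal LAMMPS dump subset


def _read_lammps_dump(path: Path, type_map: Mapping[int, str] | None) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    nlines = len(lines)
    while i < nlines:
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise ParseError(f"expected 'ITEM: TIMESTEP', got {lines[i]!r}", i + 1)
        timestep = float(lines[i + 1].strip())
        if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise ParseError("expected 'ITEM: NUMBER OF ATOMS'", i + 3)
        n = int(lines[i + 3].strip())
        if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
            raise ParseError("expected 'ITEM: BOX BOUNDS'", i + 5)
        box = []
        for k in range(3):
            parts = lines[i + 5 + k].split()
            if len(parts) < 2:
                raise ParseError("box bounds need 'lo hi'", i + 6 + k)
            lo, hi = float(parts[0]), float(parts[1])
            box.append(hi - lo)
        header = lines[i + 8]
        if not header.startswith("ITEM: ATOMS"):
            raise ParseError("expected 'ITEM: ATOMS'", i + 9)
        cols = header.split()[2:]
        try:
            ci = {name: cols.index(name) for name in ("id", "type", "x", "y", "z")}
        except ValueError:
            raise ParseError(
                f"ATOMS columns must include id type x y z, got {cols}", i + 9
            ) from None
        records = lines[i + 9 : i + 9 + n]
        if len(records) < n:
            raise ParseError(
                f"frame declares {n} atoms but file ends after {len(records)}", nlines
            )
        ids = np.empty(n, dtype=np.int64)
        types = np.empty(n, dtype=np.int64)
        coords = np.empty((n, 3))
        for j, rec in enumerate(records):
            parts = rec.split()
            if len(parts) != len(cols):
                raise ParseError(f"expected {len(cols)} columns, got {rec!r}", i + 10 + j)
            ids[j] = int(parts[ci["id"]])
            types[j] = int(parts[ci["type"]])
            coords[j] = [
                float(parts[ci["x"]]),
                float(parts[ci["y"]]),
                float(parts[ci["z"]]),
            ]
        order = np.argsort(ids, kind="stable")
        types = types[order]
        coords = coords[order]
        if type_map is not None:
            species = np.array([type_map[int(t)] for t in types])
        else:
            species = types.astype(str)
        frames.append(Frame(coords, species, tuple(box), timestep))
        i += 9 + n
    if not frames:
        raise ParseError("file contains no frames", 1)
    return frames


def _write_lammps_dump(
    traj: Trajectory, path: Path, type_map: Mapping[int, str] | None = None
) -> None:
    # species -> integer type; caller's mapping wins, else sorted order.
    if type_map is not None:
        sp_to_type = {v: k for k, v in type_map.items()}
    else:
        sp_to_type = {s: k + 1 for k, s in enumerate(sorted(traj.species_set()))}
    with open(path, "w") as fh:
        for fr in traj:
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{_FLOAT_FMT % fr.time}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{fr.n_particles}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for b in fr.box:
                half = b / 2.0
                fh.write(f"{_FLOAT_FMT % -half} {_FLOAT_FMT % half}\n")
            fh.write("ITEM: ATOMS id type x y z\n")
            for j, (sp, (x, y, z)) in enumerate(zip(fr.species, fr.coords)):
                fh.write(
                    f"{j + 1} {sp_to_type[str(sp)]} "
                    f"{_FLOAT_FMT % x} {_FLOAT_FMT % y} {_FLOAT_FMT % z}\n"
                )


TRAJ_FORMATS = ("xyz-ext", "lammps-dump")


def read_trajectory(
    path: str | Path,
    format: str = "xyz-ext",
    type_map: Mapping[int, str] | None = None,
) -> Trajectory:
    """Read a trajectory in one of the supported textual dialects.

    Parameters
    ----------
    path
        Input file.
    format
        ``"xyz-ext"`` or ``"lammps-dump"``.
    type_map
        For LAMMPS dumps: mapping from integer atom type to species tag.
    """
    path = Path(path)
    if format == "xyz-ext":
        frames = _read_xyz(path)
    elif format == "lammps-dump":
        frames = _read_lammps_dump(path, type_map)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(frames)


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    format: str = "xyz-ext",
    type_map: Mapping[int, str] | None = None,
) -> None:
    path = Path(path)
    if format == "xyz-ext":
        _write_xyz(traj, path)
    elif format == "lammps-dump":
        _write_lammps_dump(traj, path, type_map)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


# --------------------------------------------------------------------------
# pressure-tensor series and wall-force logs (CSV)

_PRESSURE_COLS = ("time", "pxx", "pyy", "pzz")


def read_pressure_series(
    path: str | Path,
    box_lz: float | None = None,
    units: str = "reduced",
) -> PressureTensorSeries:
    """Read a pressure-tensor CSV (columns time,pxx,pyy,pzz).

    ``box_lz`` may be given explicitly or stored in the file as a leading
    comment line ``# box_lz = <value>``.
    """
    path = Path(path)
    if box_lz is None:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "box_lz" in line:
                    box_lz = float(line.split("=", 1)[1])
                    break
    if box_lz is None:
        raise SchemaError("box_lz not given and not found in a header comment")
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _PRESSURE_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"pressure CSV missing columns: {missing}")
    return PressureTensorSeries(
        df["time"].to_numpy(),
        df["pxx"].to_numpy(),
        df["pyy"].to_numpy(),
        df["pzz"].to_numpy(),
        box_lz=box_lz,
        units=units,
    )


def write_pressure_series(series: PressureTensorSeries, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time": series.times,
            "pxx": series.pxx,
            "pyy": series.pyy,
            "pzz": series.pzz,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# box_lz = {_FLOAT_FMT % series.box_lz}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_wall_force_log(path: str | Path) -> pd.DataFrame:
    """Read a wall-force CSV (columns time, f_total, optional f_<species>)."""
    df = pd.read_csv(path, comment="#")
    for col in ("time", "f_total"):
        if col not in df.columns:
            raise SchemaError(f"wall-force CSV missing column {col!r}")
    return df


def write_wall_force_log(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# --------------------------------------------------------------------------
# isotherm JSON


def write_isotherm(isotherm, path: str | Path) -> None:
    """Serialize an :class:`~isopress.isotherm.Isotherm` to JSON."""
    if not isotherm.points:
        raise ValueError("cannot write an empty isotherm")
    payload = {
        "units": isotherm.units,
        "temperature": isotherm.temperature,
        "direction": isotherm.direction,
        "points": [
            {
                "area_per_lipid": p.area_per_lipid,
                "pi_ideal": p.pi_ideal,
                "pi_ideal_err": p.pi_ideal_err,
                "pi_real": p.pi_real,
                "pi_real_err": p.pi_real_err,
                "pi_tensor": p.pi_tensor,
                "pi_tensor_err": p.pi_tensor_err,
                "xi": p.xi,
                "lz_int": p.lz_int,
                "equilibrated": p.equilibrated,
            }
            for p in isotherm.points
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_isotherm(path: str | Path):
    """Read an isotherm JSON written by :func:`write_isotherm`."""
    from .isotherm import Isotherm, IsothermPoint  # local import: avoid cycle

    with open(path) as fh:
        payload = json.load(fh)
    for key in ("units", "direction", "points"):
        if key not in payload:
            raise SchemaError(f"isotherm JSON missing field {key!r}")
    points = [IsothermPoint(**p) for p in payload["points"]]
    return Isotherm(
        points=points,
        units=payload["units"],
        temperature=payload.get("temperature"),
        direction=payload["direction"],
    )
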