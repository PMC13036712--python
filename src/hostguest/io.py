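"""Readers and writers for the package's plain-text formats.

Formats: titration CSV (totals + signal, '#' comments, molar or
micromolar), quantum-yield CSV (absorbance, integrated intensity),
two-column TCSPC decay text, excitation TSV (position, unit, f),
multi-frame XYZ with a box comment line, and Gaussian cube files for
scalar grids. Readers validate and reject malformed input rather than
silently coercing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .density_topology import BOHR_PER_ANGSTROM
from .equilibria import TitrationSeries
from .photophysics import DecayTrace
from .spectra import Excitation, ExcitationTable
from .solvation import Trajectory

__all__ = [
    "read_titration",
    "write_titration",
    "read_qy_pairs",
    "read_decay",
    "write_decay",
    "read_excitations",
    "write_excitations",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "write_cube",
    "read_cube",
    "RunConfig",
    "load_config",
]

_TITRATION_COLUMNS = ("host_total_M", "indicator_total_M", "competitor_total_M", "signal")


def read_titration(path: str | Path, units: str | None = None) -> TitrationSeries:
    """Read a titration CSV into molar units.

    Required columns: host_total_M, indicator_total_M, competitor_total_M,
    signal. '#' comment lines are allowed; a ``# units: uM`` comment (or
    ``units='uM'``) declares micromolar concentrations, converted on read.
    The mode is inferred from which total is swept.
    """
    path = Path(path)
    if units is None:
        units = "M"
        for line in path.read_text().splitlines():
            if line.startswith("#") and "units:" in line:
                units = line.split("units:", 1)[1].strip()
            if not line.startswith("#"):
                break
    if units not in ("M", "uM"):
        raise ValueError(f"units must be 'M' or 'uM', got {units!r}")
    df = pd.read_csv(path, comment="#")
    for col in _TITRATION_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"titration file is missing required column {col!r}")
    scale = 1e-6 if units == "uM" else 1.0
    conc = df[list(_TITRATION_COLUMNS[:3])].to_numpy(dtype=float) * scale
    bad = np.nonzero(conc < 0)[0]
    if len(bad):
        raise ValueError(f"negative concentration in data row {int(bad[0])}")
    mode = (
        "competitor_titration"
        if np.ptp(conc[:, 2]) > 0 and np.ptp(conc[:, 0]) == 0
        else "host_titration"
    )
    return TitrationSeries(
        H_total=conc[:, 0],
        I_total=conc[:, 1],
        G_total=conc[:, 2],
        signal=df["signal"].to_numpy(dtype=float),
        mode=mode,
    )


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    """Write a titration series as the molar CSV dialect ``read_titration`` expects."""
    df = pd.DataFrame(
        {
            "host_total_M": series.H_total,
            "indicator_total_M": series.I_total,
            "competitor_total_M": series.G_total,
            "signal": series.signal,
        }
    )
    with open(path, "w") as fh:
        fh.write("# units: M\n")
        df.to_csv(fh, index=False)


def read_qy_pairs(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read (absorbance, integrated_intensity) CSV for quantum-yield slopes."""
    df = pd.read_csv(path, comment="#")
    for col in ("absorbance", "integrated_intensity"):
        if col not in df.columns:
            raise ValueError(f"QY file is missing required column {col!r}")
    return (
        df["absorbance"].to_numpy(dtype=float),
        df["integrated_intensity"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# decay traces


def _read_two_column(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two whitespace-separated columns")
    return data[:, 0], data[:, 1]


def read_decay(decay_path: str | Path, irf_path: str | Path) -> DecayTrace:
    """Assemble a DecayTrace from decay and IRF two-column (time_ns, counts) files."""
    t, counts = _read_two_column(decay_path)
    t_irf, irf = _read_two_column(irf_path)
    if len(t) != len(t_irf) or not np.allclose(t, t_irf):
        raise ValueError("decay and IRF must share the same time axis")
    widths = np.diff(t)
    if len(widths) == 0 or not np.allclose(widths, widths[0], rtol=1e-6):
        raise ValueError("time bins must be uniform")
    w = widths[0]
    edges = np.concatenate([t - 0.5 * w, [t[-1] + 0.5 * w]])
    return DecayTrace(bin_edges=edges, counts=counts, irf_counts=irf)


def write_decay(trace: DecayTrace, decay_path: str | Path, irf_path: str | Path) -> None:
    """Write a DecayTrace as paired two-column text files (bin centres, counts)."""
    t = trace.centers
    np.savetxt(decay_path, np.column_stack([t, trace.counts]), fmt="%.6f %.1f")
    np.savetxt(irf_path, np.column_stack([t, trace.irf_counts]), fmt="%.6f %.4f")


# ---------------------------------------------------------------------------
# excitations


def read_excitations(path: str | Path, label: str | None = None) -> ExcitationTable:
    """Read an excitation TSV with columns position, unit (nm|cm-1|eV), f."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("position", "unit", "f"):
        if col not in df.columns:
            raise ValueError(f"excitation file is missing required column {col!r}")
    exc = []
    for _, row in df.iterrows():
        unit = str(row["unit"])
        if unit == "nm":
            exc.append(Excitation.from_nm(float(row["position"]), float(row["f"])))
        elif unit == "cm-1":
            exc.append(Excitation(float(row["position"]), float(row["f"])))
        elif unit == "eV":
            exc.append(Excitation.from_ev(float(row["position"]), float(row["f"])))
        else:
            raise ValueError(f"unknown position unit {unit!r}")
    return ExcitationTable(tuple(exc), label=label or Path(path).stem)


def write_excitations(table: ExcitationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tunit\tf\n")
        for e in table.excitations:
            fh.write(f"{e.position:.6f}\tcm-1\t{e.f:.8f}\n")


# ---------------------------------------------------------------------------
# trajectories (multi-frame XYZ dialect with a box comment line)


def read_xyz_trajectory(path: str | Path) -> Trajectory:
    """Read the package's multi-frame XYZ dialect.

    Per frame: atom count line; a comment line containing ``box Lx Ly Lz``
    (A); then one ``label x y z`` line per atom. The box and atom count
    must be identical across frames.
    """
    lines = Path(path).read_text().splitlines()
    i = 0
    frames, labels, box = [], None, None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        if "box" not in comment:
            raise ValueError("frame comment line must carry 'box Lx Ly Lz'")
        parts = comment.split()
        b = np.array([float(x) for x in parts[parts.index("box") + 1:][:3]])
        frame_labels, coords = [], []
        for j in range(n):
            tok = lines[i + 2 + j].split()
            frame_labels.append(tok[0])
            coords.append([float(x) for x in tok[1:4]])
        if labels is None:
            labels, box = frame_labels, b
        elif frame_labels != labels or not np.allclose(b, box):
            raise ValueError("atom labels and box must be constant across frames")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError("no frames found")
    return Trajectory(labels=tuple(labels), frames=np.array(frames, dtype=float), box=box)


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"box {traj.box[0]:.6f} {traj.box[1]:.6f} {traj.box[2]:.6f}\n")
            for label, (x, y, z) in zip(traj.labels, frame):
                fh.write(f"{label} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Gaussian cube files


def write_cube(
    grid: np.ndarray,
    origin: np.ndarray,
    voxel: float,
    atoms: list[tuple[int, np.ndarray]],
    path: str | Path,
    units: str = "bohr",
    comment: str = "scalar field",
) -> None:
    """Write a 3D scalar grid in the Gaussian cube layout.

    ``origin`` and ``voxel`` are in the given units; per the cube
    convention, Angstrom input is flagged by negative axis counts and the
    numbers themselves are written converted to bohr. ``atoms`` is a list
    of (atomic number, position) in the same units. Values are written
    with the last (z) axis fastest.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 3:
        raise ValueError("grid must be 3-dimensional")
    origin = np.asarray(origin, dtype=float)
    if units not in ("bohr", "angstrom"):
        raise ValueError("units must be 'bohr' or 'angstrom'")
    to_bohr = BOHR_PER_ANGSTROM if units == "angstrom" else 1.0
    sign = -1 if units == "angstrom" else 1
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(f"{comment}\n")
        fh.write("generated by hostguest\n")
        o = origin * to_bohr
        fh.write(f"{len(atoms):5d} {o[0]:12.6f} {o[1]:12.6f} {o[2]:12.6f}\n")
        v = voxel * to_bohr
        fh.write(f"{sign * nx:5d} {v:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        fh.write(f"{sign * ny:5d} {0.0:12.6f} {v:12.6f} {0.0:12.6f}\n")
        fh.write(f"{sign * nz:5d} {0.0:12.6f} {0.0:12.6f} {v:12.6f}\n")
        for Z, pos in atoms:
            p = np.asarray(pos, dtype=float) * to_bohr
            fh.write(f"{Z:5d} {float(Z):12.6f} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}\n")
        flat = grid.reshape(nx * ny, nz)
        for row in flat:
            for k in range(0, nz, 6):
                fh.write("".join(f"{x:13.5E}" for x in row[k:k + 6]) + "\n")


def read_cube(path: str | Path):
    """Read a Gaussian cube file written by :func:`write_cube`.

    Returns (grid, origin, voxel, atoms, units); negative axis counts are
    interpreted, per the format convention, as Angstrom-flagged input and
    the returned origin/voxel/atom positions are converted back to A.
    """
    lines = Path(path).read_text().splitlines()
    natoms = int(lines[2].split()[0])
    origin = np.array([float(x) for x in lines[2].split()[1:4]])
    counts, voxels = [], []
    for k in range(3):
        parts = lines[3 + k].split()
        counts.append(int(parts[0]))
        voxels.append(float(parts[1 + k]))
    units = "angstrom" if counts[0] < 0 else "bohr"
    from_bohr = 1.0 / BOHR_PER_ANGSTROM if units == "angstrom" else 1.0
    shape = tuple(abs(c) for c in counts)
    if len(set(voxels)) > 1 and not np.allclose(voxels, voxels[0]):
        raise ValueError("only cubic voxels are supported")
    atoms = []
    for k in range(natoms):
        parts = lines[6 + k].split()
        atoms.append((int(parts[0]), np.array([float(x) for x in parts[2:5]]) * from_bohr))
    values = []
    for line in lines[6 + natoms:]:
        values.extend(float(x) for x in line.split())
    grid = np.array(values).reshape(shape)
    return grid, origin * from_bohr, voxels[0] * from_bohr, atoms, units


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one simulation/analysis stage.

    Top-level keys: ``kind``, ``seed``, ``parameters``, ``out``; unknown
    keys (at either level, for generators with introspectable signatures)
    are rejected rather than ignored.
    """

    kind: str
    seed: int
    parameters: dict
    out: str | None = None

    _KINDS = ("titration", "ida", "decay", "excitations", "solvation")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if not isinstance(self.seed, int):
            raise ValueError("seed is mandatory and must be an integer")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    allowed = {"kind", "seed", "parameters", "out"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("config must set a seed")
    return RunConfig(
        kind=raw.get("kind", ""),
        seed=raw["seed"],
        parameters=raw.get("parameters", {}) or {},
        out=raw.get("out"),
    )
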