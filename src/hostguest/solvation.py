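"""Solvation-shell statistics from classical MD trajectories.

Operates on orthorhombic-box trajectories under the minimum-image
convention: radial distribution functions g(r) with first-shell
coordination numbers, geometric hydrogen-bond detection, extraction of a
finite "nanodroplet" of waters around a solute (with the H-bonded subset
tagged for quantum-mechanical treatment in QM/MM workflows), and 3D
solvent-occupancy maps.

The hydrogen-bond criterion is purely geometric: acceptor–donor heavy-atom
distance <= 3.5 A and an angle cutoff of 30 degrees. The angle vertex is
at the donor, between the donor->acceptor and donor->hydrogen directions
(a small angle then means a near-linear D-H...A arrangement); the
alternative vertex-at-hydrogen convention is selectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "RDFResult",
    "HBondCriteria",
    "rdf",
    "first_shell",
    "hbond_partners",
    "extract_nanodroplet",
    "occupancy_map",
    "ATOMIC_MASSES",
]

#: Standard atomic masses used for water centers of mass.
ATOMIC_MASSES = {"O": 15.999, "H": 1.008, "N": 14.007, "C": 12.011, "S": 32.06}


@dataclass(frozen=True)
class Trajectory:
    """Frames of labelled coordinates (A) in an orthorhombic periodic box."""

    labels: tuple[str, ...]
    frames: np.ndarray  # (n_frames, n_atoms, 3) A
    box: np.ndarray  # (3,) A
    timestep_ps: float = 0.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "box", np.asarray(self.box, dtype=float))
        object.__setattr__(self, "labels", tuple(self.labels))
        if frames.shape[1] != len(self.labels):
            raise ValueError("labels do not match atom count")
        if not np.all(np.isfinite(frames)):
            raise ValueError("coordinates must be finite")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive lengths")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def select(self, labels: str | list[str] | None = None,
               indices: list[int] | None = None) -> np.ndarray:
        """Atom indices by label(s) or an explicit index list."""
        if indices is not None:
            return np.asarray(indices, dtype=int)
        if labels is None:
            return np.arange(self.n_atoms)
        if isinstance(labels, str):
            labels = [labels]
        wanted = set(labels)
        return np.array([i for i, l in enumerate(self.labels) if l in wanted], dtype=int)


@dataclass(frozen=True)
class RDFResult:
    """g(r) on bin centres plus, once analysed, the first-shell summary."""

    r_centers: np.ndarray  # A
    g: np.ndarray
    number_density_B: float  # A^-3
    shell: tuple[float, float, float] | None = None  # (r_max, r_min, N_coord)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond cutoffs: angle (deg) and heavy-atom distance (A)."""

    max_angle: float = 30.0
    max_distance: float = 3.5
    vertex: str = "donor"  # or "hydrogen"

    def __post_init__(self) -> None:
        if not 0 < self.max_angle <= 180:
            raise ValueError("max_angle must lie in (0, 180]")
        if not self.max_distance > 0:
            raise ValueError("max_distance must be positive")
        if self.vertex not in ("donor", "hydrogen"):
            raise ValueError("vertex must be 'donor' or 'hydrogen'")


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# radial distribution


def rdf(
    traj: Trajectory,
    selection_A: np.ndarray,
    selection_B: np.ndarray,
    r_max: float,
    bin_width: float = 0.05,
) -> RDFResult:
    """Radial distribution function g(r) between two atom selections.

    Pair distances use the minimum-image convention; the histogram is
    normalised by the ideal-gas expectation n_A * rho_B * 4/3 pi (r2^3 -
    r1^3) per frame, with atoms common to both selections excluded from
    pairing with themselves.
    """
    A = np.asarray(selection_A, dtype=int)
    B = np.asarray(selection_B, dtype=int)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("selections must be non-empty")
    if r_max >= 0.5 * traj.box.min():
        raise ValueError(
            f"r_max = {r_max} A exceeds half the smallest box length "
            f"({0.5 * traj.box.min():.3f} A)"
        )
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    for frame in traj.frames:
        d = _min_image(frame[A][:, None, :] - frame[B][None, :, :], traj.box)
        dist = np.linalg.norm(d, axis=-1)
        same = A[:, None] == B[None, :]
        dist = dist[~same]
        hist += np.histogram(dist, bins=edges)[0]
    vol = np.prod(traj.box)
    rho_B = len(B) / vol
    shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = traj.n_frames * len(A) * rho_B * shell_vol
    g = np.divide(hist, ideal, out=np.zeros_like(hist), where=ideal > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return RDFResult(r_centers=centers, g=g, number_density_B=rho_B)


def first_shell(
    result: RDFResult,
    number_density_B: float | None = None,
    smooth: bool = True,
) -> tuple[float, float, float]:
    """First-shell peak, following minimum, and coordination number.

    Extrema are read off a 3-point moving average of g by default (raw g
    with ``smooth=False``); the coordination number integrates
    4 pi rho_B g(r) r^2 up to the first minimum by the trapezoid rule.
    """
    rho_B = result.number_density_B if number_density_B is None else number_density_B
    r, g = result.r_centers, result.g
    gs = g
    if smooth and len(g) >= 3:
        gs = np.convolve(g, np.ones(3) / 3.0, mode="same")
    # first interior local maximum with non-negligible height
    imax = None
    for i in range(1, len(gs) - 1):
        if gs[i] > gs[i - 1] and gs[i] >= gs[i + 1] and gs[i] > 1e-12:
            imax = i
            break
    if imax is None:
        raise ValueError("g(r) has no interior maximum; no first shell found")
    imin = None
    for i in range(imax + 1, len(gs) - 1):
        if gs[i] <= gs[i - 1] and gs[i] < gs[i + 1]:
            imin = i
            break
    if imin is None:
        # g decays to zero (isolated shell): integrate to the first empty bin
        zero = np.nonzero(gs[imax:] <= 1e-12)[0]
        if len(zero) == 0:
            raise ValueError("no minimum after the first peak within r_max")
        imin = imax + int(zero[0])
    mask = r <= r[imin]
    n_coord = 4.0 * math.pi * rho_B * np.trapezoid(g[mask] * r[mask] ** 2, r[mask])
    return float(r[imax]), float(r[imin]), float(n_coord)


# ---------------------------------------------------------------------------
# hydrogen bonds


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def hbond_partners(
    frame: np.ndarray,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
    box: np.ndarray | None = None,
) -> list[tuple[int, int, int]]:
    """Hydrogen-bonded (donor, hydrogen, acceptor) triples in one frame.

    ``hydrogens[k]`` is the hydrogen covalently mapped to ``donors[k]``
    (the two arrays run in parallel; a donor with two hydrogens appears
    twice). A triple is selected when the acceptor–donor minimum-image
    distance is within the cutoff and the criterion angle is within the
    angular cutoff.
    """
    frame = np.asarray(frame, dtype=float)
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if len(donors) != len(hydrogens):
        raise ValueError("each hydrogen must be mapped to its donor "
                         "(donors and hydrogens must align)")
    out: list[tuple[int, int, int]] = []
    for d, h in zip(donors, hydrogens):
        for a in acceptors:
            if a == d or a == h:
                continue
            da = frame[a] - frame[d]
            dh = frame[h] - frame[d]
            if box is not None:
                da = _min_image(da, np.asarray(box, dtype=float))
                dh = _min_image(dh, np.asarray(box, dtype=float))
            if np.linalg.norm(da) > criteria.max_distance:
                continue
            if criteria.vertex == "donor":
                ang = _angle_deg(da, dh)
            else:  # vertex at the hydrogen: deviation of D-H...A from linear
                ang = 180.0 - _angle_deg(-dh, da - dh)
            if ang <= criteria.max_angle:
                out.append((int(d), int(h), int(a)))
    return out


# ---------------------------------------------------------------------------
# nanodroplet extraction


def extract_nanodroplet(
    traj: Trajectory,
    frame_index: int,
    solute_indices: np.ndarray,
    water_groups: list[tuple[int, int, int]],
    radius: float = 20.0,
    criteria: HBondCriteria = HBondCriteria(),
    solute_donors: np.ndarray | None = None,
    solute_hydrogens: np.ndarray | None = None,
    solute_acceptors: np.ndarray | None = None,
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    """Carve a spherical water droplet around the solute and split QM/MM.

    Waters (``water_groups`` of (O, H, H) atom indices) whose centre of
    mass lies within ``radius`` A of the solute geometric (unweighted)
    centre are retained. Retained waters hydrogen-bonded to the solute in
    either direction — water donating to a solute acceptor, or a solute
    donor donating to the water oxygen — are returned as the QM set, the
    rest as the MM set; the two sets partition the retained waters.
    """
    if len(solute_indices) == 0:
        raise ValueError("solute selection must be non-empty")
    frame = traj.frames[frame_index]
    center = frame[np.asarray(solute_indices, dtype=int)].mean(axis=0)
    mass = np.array([ATOMIC_MASSES["O"], ATOMIC_MASSES["H"], ATOMIC_MASSES["H"]])
    retained = []
    for grp in water_groups:
        com = (mass[:, None] * frame[list(grp)]).sum(axis=0) / mass.sum()
        if np.linalg.norm(_min_image(com - center, traj.box)) <= radius:
            retained.append(grp)
    sd = np.asarray([] if solute_donors is None else solute_donors, dtype=int)
    sh = np.asarray([] if solute_hydrogens is None else solute_hydrogens, dtype=int)
    sa = np.asarray([] if solute_acceptors is None else solute_acceptors, dtype=int)
    qm, mm = [], []
    for grp in retained:
        o, h1, h2 = grp
        bonded = bool(
            hbond_partners(frame, np.array([o, o]), np.array([h1, h2]), sa,
                           criteria, traj.box)
        ) or bool(
            hbond_partners(frame, sd, sh, np.array([o]), criteria, traj.box)
        )
        (qm if bonded else mm).append(grp)
    return qm, mm


# ---------------------------------------------------------------------------
# occupancy maps


def occupancy_map(
    traj: Trajectory,
    selection: np.ndarray,
    voxel: float = 0.5,
    origin: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel position counts of a selection accumulated over frames.

    Returns (grid, origin); the grid spans the box from ``origin``
    (default zero) with cubic voxels of edge ``voxel`` A, and its total
    equals n_selected * n_frames (positions are wrapped into the box).
    """
    if not voxel > 0:
        raise ValueError("voxel must be positive")
    sel = np.asarray(selection, dtype=int)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    shape = tuple(int(math.ceil(b / voxel)) for b in traj.box)
    grid = np.zeros(shape)
    for frame in traj.frames:
        pos = np.mod(frame[sel] - origin, traj.box)
        idx = np.minimum((pos / voxel).astype(int), np.array(shape) - 1)
        np.add.at(grid, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return grid, origin
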