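"""Electron-density topology: QTAIM descriptors, bond critical points, NCI.

The density source is a deliberately minimal wavefunction model — molecular
orbitals expanded in s-type Gaussian primitives with occupation numbers:

    rho(r) = Sum_i eta_i |phi_i(r)|^2,
    phi_i(r) = Sum_k C_ik c_k exp(-alpha_k |r - A_k|^2)

which makes rho and all of its derivatives analytic. Local descriptors
(atomic units throughout):

    G(r) = 1/2 Sum_i eta_i |grad phi_i|^2          kinetic energy density
    V(r) = 1/4 lap(rho) - 2 G(r)                   local virial theorem
    H(r) = G(r) + V(r)                             total energy density
    s(r) = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))   reduced density gradient

Bond critical points are (3,-1) stationary points of rho located by a
damped Newton search on grad rho seeded from bond midpoints. An
interaction at a BCP is classified noncovalent when lap(rho) > 0, H > 0
and -G/V > 1, the closed-shell signature; a quick hydrogen-bond energy
estimate follows the linear calibration

    B_E (kcal/mol) = -223.08 rho_bcp + 0.7423,

valid for H-bond densities roughly in 0.002–0.04 e a0^-3. NCI grids pair
s(r) with sign(lambda2) rho(r) (lambda2 the middle Hessian eigenvalue):
low-s/low-rho regions mark noncovalent contacts, negative lambda2
attractive, positive repulsive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavefunctionModel",
    "FieldPoint",
    "CriticalPoint",
    "NCIGrid",
    "load_wavefunction",
    "packaged_wavefunction",
    "eval_field",
    "rdg",
    "find_bcps",
    "classify_interaction",
    "be_from_rho",
    "nci_grid",
    "BOHR_PER_ANGSTROM",
]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

_RDG_CONST = 2.0 * (3.0 * math.pi**2) ** (1.0 / 3.0)


@dataclass(frozen=True)
class WavefunctionModel:
    """Molecular orbitals over s-type Gaussian primitives.

    centers: (n_centers, 3) bohr; atomic_numbers: per center (for export);
    primitives: each basis function is one primitive (center index,
    exponent alpha, coefficient incl. normalisation); mo_coefficients:
    (n_mo, n_basis); occupations: eta_i >= 0 summing to the electron count.
    """

    centers: np.ndarray
    atomic_numbers: tuple[int, ...]
    primitive_centers: np.ndarray  # (n_basis,) int
    exponents: np.ndarray  # (n_basis,)
    coefficients: np.ndarray  # (n_basis,)
    mo_coefficients: np.ndarray  # (n_mo, n_basis)
    occupations: np.ndarray  # (n_mo,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.asarray(self.centers, dtype=float))
        object.__setattr__(self, "primitive_centers",
                           np.asarray(self.primitive_centers, dtype=int))
        for name in ("exponents", "coefficients", "occupations"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "mo_coefficients",
                           np.atleast_2d(np.asarray(self.mo_coefficients, dtype=float)))
        if np.any(self.occupations < 0):
            raise ValueError("occupations must be >= 0")
        if np.any(self.exponents <= 0):
            raise ValueError("exponents must be positive")
        if self.primitive_centers.max(initial=-1) >= len(self.centers):
            raise ValueError("primitive center index out of range")

    @property
    def n_electrons(self) -> float:
        return float(self.occupations.sum())


@dataclass(frozen=True)
class FieldPoint:
    """All local density descriptors at one point (atomic units)."""

    rho: float
    grad: np.ndarray  # (3,)
    hessian: np.ndarray  # (3, 3)
    G: float
    V: float
    H: float
    s: float
    lambda2: float

    @property
    def laplacian(self) -> float:
        return float(np.trace(self.hessian))

    @property
    def signed_rho(self) -> float:
        """sign(lambda2) * rho, the NCI colouring variable."""
        return math.copysign(1.0, self.lambda2) * self.rho


@dataclass(frozen=True)
class CriticalPoint:
    """A stationary point of rho with its signature and local descriptors."""

    position: np.ndarray
    rank: int
    signature: int
    field: FieldPoint
    atoms: tuple[int, int]
    degenerate: bool = False

    @property
    def kind(self) -> tuple[int, int]:
        return (self.rank, self.signature)


# ---------------------------------------------------------------------------
# field evaluation


def _mo_values(model: WavefunctionModel, point: np.ndarray):
    """phi, grad phi (n_mo,3) and Hessian contributions at one point."""
    u = point[None, :] - model.centers[model.primitive_centers]  # (nb, 3)
    r2 = np.einsum("kj,kj->k", u, u)
    g = model.coefficients * np.exp(-model.exponents * r2)  # (nb,)
    # d g / dx = -2 alpha u g ; Hessian = (4 a^2 u u^T - 2 a I) g
    a = model.exponents
    dg = (-2.0 * a * g)[:, None] * u  # (nb, 3)
    uuT = np.einsum("ki,kj->kij", u, u)
    d2g = (4.0 * a**2 * g)[:, None, None] * uuT
    d2g -= (2.0 * a * g)[:, None, None] * np.eye(3)[None, :, :]
    C = model.mo_coefficients  # (nmo, nb)
    phi = C @ g  # (nmo,)
    dphi = C @ dg  # (nmo, 3)
    d2phi = np.einsum("ik,kab->iab", C, d2g)  # (nmo, 3, 3)
    return phi, dphi, d2phi


def eval_field(model: WavefunctionModel, point: np.ndarray) -> FieldPoint:
    """Analytic rho, derivatives and energy densities at one point.

    V comes from the local virial theorem V = 1/4 lap(rho) - 2G, so
    H = G + V holds by construction; far-field underflow returns zeros.
    """
    point = np.asarray(point, dtype=float)
    phi, dphi, d2phi = _mo_values(model, point)
    eta = model.occupations
    rho = float(eta @ phi**2)
    grad = 2.0 * np.einsum("i,i,ia->a", eta, phi, dphi)
    hess = 2.0 * np.einsum("i,ia,ib->ab", eta, dphi, dphi)
    hess += 2.0 * np.einsum("i,i,iab->ab", eta, phi, d2phi)
    G = 0.5 * float(np.einsum("i,ia,ia->", eta, dphi, dphi))
    lap = float(np.trace(hess))
    V = 0.25 * lap - 2.0 * G
    H = G + V
    gnorm = float(np.linalg.norm(grad))
    s = rdg(rho, gnorm) if rho > 0 else 0.0
    lam = np.linalg.eigvalsh(0.5 * (hess + hess.T))
    return FieldPoint(rho=rho, grad=grad, hessian=hess, G=G, V=V, H=H, s=s,
                      lambda2=float(lam[1]))


def rdg(rho: float, grad_norm: float) -> float:
    """Reduced density gradient s = |grad rho| / (2 (3 pi^2)^(1/3) rho^(4/3))."""
    if not rho > 0:
        raise ValueError(f"rho must be positive, got {rho}")
    return grad_norm / (_RDG_CONST * rho ** (4.0 / 3.0))


# ---------------------------------------------------------------------------
# critical points


def _newton_cp(model: WavefunctionModel, x0: np.ndarray,
               tol: float = 1e-10, max_iter: int = 100) -> np.ndarray | None:
    """Damped Newton search for a stationary point of rho from x0."""
    x = np.asarray(x0, dtype=float).copy()
    fp = eval_field(model, x)
    gnorm = np.linalg.norm(fp.grad)
    for _ in range(max_iter):
        if gnorm < tol:
            return x
        try:
            step = np.linalg.solve(fp.hessian, -fp.grad)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(step)):
            return None
        # damp by halving while the gradient norm overshoots
        lam = 1.0
        for _ in range(30):
            trial = x + lam * step
            fp_t = eval_field(model, trial)
            gn_t = np.linalg.norm(fp_t.grad)
            if gn_t < gnorm or gn_t < tol:
                break
            lam *= 0.5
        else:
            return None
        x, fp, gnorm = trial, fp_t, gn_t
    return x if gnorm < tol else None


def find_bcps(
    model: WavefunctionModel,
    atom_pairs: list[tuple[int, int]] | None = None,
    merge_tol: float = 1e-4,
) -> list[CriticalPoint]:
    """Locate critical points of rho seeded from bond midpoints.

    ``atom_pairs=None`` seeds from every distinct center pair. Converged
    points closer than ``merge_tol`` bohr are merged; pairs whose search
    does not converge are simply absent from the result. Signatures use a
    Hessian-eigenvalue zero threshold of 1e-10 (near-zero eigenvalues flag
    the point degenerate).
    """
    n = len(model.centers)
    if atom_pairs is None:
        atom_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    found: list[CriticalPoint] = []
    for i, j in atom_pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"atom pair ({i}, {j}) out of range")
        mid = 0.5 * (model.centers[i] + model.centers[j])
        pos = _newton_cp(model, mid)
        if pos is None:
            continue
        if any(np.linalg.norm(pos - cp.position) < merge_tol for cp in found):
            continue
        fp = eval_field(model, pos)
        eig = np.linalg.eigvalsh(0.5 * (fp.hessian + fp.hessian.T))
        thr = 1e-10
        nonzero = np.abs(eig) > thr
        rank = int(nonzero.sum())
        signature = int(np.sign(eig[nonzero]).sum()) if rank else 0
        found.append(
            CriticalPoint(
                position=pos,
                rank=rank,
                signature=signature,
                field=fp,
                atoms=(i, j),
                degenerate=rank < 3,
            )
        )
    return found


def classify_interaction(cp: CriticalPoint) -> str:
    """Closed-shell vs shared classification of a (3,-1) bond critical point.

    'noncovalent' iff lap(rho) > 0, H > 0 and -G/V > 1 (kinetic energy
    locally dominates the potential stabilisation); 'shared' otherwise.
    """
    if cp.kind != (3, -1):
        raise ValueError(f"classification requires a (3,-1) CP, got {cp.kind}")
    f = cp.field
    ratio = -f.G / f.V if f.V != 0 else math.inf
    if f.laplacian > 0 and f.H > 0 and ratio > 1:
        return "noncovalent"
    return "shared"


#: Calibration range of the H-bond linear estimator, e a0^-3.
BE_CALIBRATION_RANGE = (0.002, 0.04)


def be_from_rho(rho_bcp: float) -> float:
    """Hydrogen-bond energy estimate from the BCP density (kcal/mol).

    Linear calibration B_E = -223.08 rho + 0.7423; warns outside the
    0.002–0.04 e a0^-3 H-bond density range it was calibrated on.
    """
    if rho_bcp < 0:
        raise ValueError("rho must be >= 0")
    lo, hi = BE_CALIBRATION_RANGE
    if not lo <= rho_bcp <= hi:
        import warnings

        warnings.warn(
            f"rho = {rho_bcp:g} e a0^-3 is outside the H-bond calibration "
            f"range [{lo}, {hi}]", stacklevel=2,
        )
    return -223.08 * rho_bcp + 0.7423


# ---------------------------------------------------------------------------
# NCI grids


@dataclass(frozen=True)
class NCIGrid:
    """RDG / signed-density grids for noncovalent-interaction plots."""

    origin: np.ndarray  # bohr
    spacing: float  # bohr
    s: np.ndarray  # (nx, ny, nz); NaN where rho exceeds rho_max
    signed_rho: np.ndarray  # raw sign(lambda2) * rho
    color: np.ndarray  # signed_rho clamped to the export colour range
    rho_max: float
    color_range: tuple[float, float]


def nci_grid(
    model: WavefunctionModel,
    box: tuple[np.ndarray, np.ndarray] | None = None,
    spacing: float = 0.25,
    rho_max: float = 0.05,
    color_range: tuple[float, float] = (-0.05, 0.01),
    padding: float = 4.0,
) -> NCIGrid:
    """Evaluate s(r) and sign(lambda2) rho(r) on a regular grid.

    ``box`` is (lower corner, upper corner) in bohr; by default the model's
    centers padded by ``padding`` bohr. Voxels with rho > rho_max (dense,
    non-NCI regions) are masked to NaN in s; the colour grid is the signed
    density clamped to ``color_range`` for export to visualizers.
    """
    if not spacing > 0:
        raise ValueError("spacing must be positive")
    if box is None:
        lo = model.centers.min(axis=0) - padding
        hi = model.centers.max(axis=0) + padding
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in box)
    if np.any(hi <= lo):
        raise ValueError("box is empty")
    if np.any(model.centers < lo) or np.any(model.centers > hi):
        raise ValueError("box must enclose all model centers")
    axes = [np.arange(lo[d], hi[d] + 0.5 * spacing, spacing) for d in range(3)]
    shape = tuple(len(a) for a in axes)
    s_grid = np.empty(shape)
    sr_grid = np.empty(shape)
    for ix, x in enumerate(axes[0]):
        for iy, y in enumerate(axes[1]):
            for iz, z in enumerate(axes[2]):
                fp = eval_field(model, np.array([x, y, z]))
                s_grid[ix, iy, iz] = fp.s if fp.rho > 0 else 0.0
                sr_grid[ix, iy, iz] = fp.signed_rho
    rho_grid = np.abs(sr_grid)
    s_masked = np.where(rho_grid > rho_max, np.nan, s_grid)
    color = np.clip(sr_grid, *color_range)
    return NCIGrid(
        origin=lo, spacing=spacing, s=s_masked, signed_rho=sr_grid,
        color=color, rho_max=rho_max, color_range=color_range,
    )


# ---------------------------------------------------------------------------
# wavefunction fixture format

_DATA_DIR = Path(__file__).parent / "data"


def load_wavefunction(path: str | Path) -> WavefunctionModel:
    """Read the package's keyed text wavefunction format.

    Layout (``#`` comments allowed)::

        centers <n>
        <Z> <x> <y> <z>        # bohr, one line per center
        basis <n>
        <center_idx> <alpha> <coeff>
        orbitals <n_mo> <n_basis>
        <occupation> <c_1> ... <c_nbasis>
    """
    tokens: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tokens.extend(line.split())
    it = iter(tokens)

    def expect(kw: str) -> None:
        got = next(it)
        if got != kw:
            raise ValueError(f"expected {kw!r}, got {got!r}")

    expect("centers")
    nc = int(next(it))
    Z, centers = [], []
    for _ in range(nc):
        Z.append(int(next(it)))
        centers.append([float(next(it)) for _ in range(3)])
    expect("basis")
    nb = int(next(it))
    pc, alpha, coeff = [], [], []
    for _ in range(nb):
        pc.append(int(next(it)))
        alpha.append(float(next(it)))
        coeff.append(float(next(it)))
    expect("orbitals")
    nmo = int(next(it))
    nb2 = int(next(it))
    if nb2 != nb:
        raise ValueError("orbital coefficient count does not match basis size")
    occ, C = [], []
    for _ in range(nmo):
        occ.append(float(next(it)))
        C.append([float(next(it)) for _ in range(nb)])
    return WavefunctionModel(
        centers=np.array(centers),
        atomic_numbers=tuple(Z),
        primitive_centers=np.array(pc),
        exponents=np.array(alpha),
        coefficients=np.array(coeff),
        mo_coefficients=np.array(C),
        occupations=np.array(occ),
    )


def packaged_wavefunction(name: str) -> WavefunctionModel:
    """Load one of the packaged model wavefunctions by short name.

    Available: ``one_center``, ``symmetric_dimer``, ``asymmetric_dimer``,
    ``noncovalent_dimer`` (all synthetic constructions, not DFT outputs).
    """
    path = _DATA_DIR / f"{name}.wfn"
    if not path.exists():
        names = sorted(p.stem for p in _DATA_DIR.glob("*.wfn"))
        raise ValueError(f"unknown wavefunction {name!r}; available: {names}")
    return load_wavefunction(path)
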