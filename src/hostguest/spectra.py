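"""UV–vis spectra from electronic-structure excitation tables.

Each vertical excitation (position nu'_if in wavenumbers, oscillator
strength f) contributes a Gaussian band of full width at half maximum
Delta nu'_1/2 to the molar absorptivity:

    eps(nu') = (2.175e8 / fwhm) * f * exp(-2.772 * (nu' - nu'_if)^2 / fwhm^2)

with eps in M^-1 cm^-1 and all wavenumbers in cm^-1. The constants
2.175e8 and 2.772 (= 4 ln 2 to three figures) are used exactly as they
appear in the broadening convention this module reproduces, not
re-derived at higher precision. The default band width is 3000 cm^-1.

Also provided: unit conversions between nm, cm^-1 and eV; the
length-gauge relation between oscillator strength and transition dipole
(f = (2/3) dE |M|^2 in atomic units); ensemble statistics over thermally
jittered snapshot tables; and Beer–Lambert molar-absorptivity fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Excitation",
    "ExcitationTable",
    "Spectrum",
    "BROADENING_PREFACTOR",
    "BROADENING_EXPONENT",
    "DEFAULT_FWHM",
    "band_epsilon",
    "convolve_spectrum",
    "convert_position",
    "dipole_from_f",
    "ensemble_stats",
    "molar_absorptivity",
]

BROADENING_PREFACTOR = 2.175e8  # M^-1 cm^-2 per unit oscillator strength
BROADENING_EXPONENT = 2.772  # 4 ln 2 to the printed precision
DEFAULT_FWHM = 3000.0  # cm^-1

_NM_CMINV = 1.0e7  # nm * cm^-1
_NM_EV = 1239.842  # nm * eV
_CMINV_PER_HARTREE = 219474.6313632  # cm^-1 per hartree


def convert_position(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a transition position between nm, cm-1 and eV.

    nm and cm^-1 (and nm and eV) are reciprocal pairs, so conversions go
    through wavelength: nu'(cm^-1) = 1e7 / lambda(nm), E(eV) = 1239.842 /
    lambda(nm).
    """
    units = {"nm", "cm-1", "eV"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"units must be one of {sorted(units)}")
    if not value > 0:
        raise ValueError(f"position must be positive, got {value}")
    # to nm first
    if from_unit == "nm":
        nm = value
    elif from_unit == "cm-1":
        nm = _NM_CMINV / value
    else:
        nm = _NM_EV / value
    if to_unit == "nm":
        return nm
    if to_unit == "cm-1":
        return _NM_CMINV / nm
    return _NM_EV / nm


@dataclass(frozen=True)
class Excitation:
    """One electronic transition: position in cm^-1 and oscillator strength."""

    position: float  # cm^-1
    f: float

    def __post_init__(self) -> None:
        if not self.position > 0:
            raise ValueError("position must be positive")
        if self.f < 0:
            raise ValueError("oscillator strength must be >= 0")

    @classmethod
    def from_nm(cls, nm: float, f: float) -> "Excitation":
        return cls(convert_position(nm, "nm", "cm-1"), f)

    @classmethod
    def from_ev(cls, ev: float, f: float) -> "Excitation":
        return cls(convert_position(ev, "eV", "cm-1"), f)

    @property
    def nm(self) -> float:
        return convert_position(self.position, "cm-1", "nm")


@dataclass(frozen=True)
class ExcitationTable:
    """The excitations of one electronic-structure run or MD snapshot."""

    excitations: tuple[Excitation, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "excitations", tuple(self.excitations))

    def __len__(self) -> int:
        return len(self.excitations)


@dataclass(frozen=True)
class Spectrum:
    """Molar absorptivity on a strictly increasing wavenumber grid."""

    grid: np.ndarray  # cm^-1
    epsilon: np.ndarray  # M^-1 cm^-1
    fwhm: float  # cm^-1

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        eps = np.asarray(self.epsilon, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "epsilon", eps)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(eps < -1e-300):
            raise ValueError("epsilon must be non-negative")

    @property
    def lambda_max_nm(self) -> float:
        """Wavelength of the absorptivity maximum."""
        return convert_position(float(self.grid[np.argmax(self.epsilon)]), "cm-1", "nm")


def default_grid(lo: float = 10_000.0, hi: float = 50_000.0,
                 step: float = 10.0) -> np.ndarray:
    """The default wavenumber grid: 10,000–50,000 cm^-1 at 10 cm^-1."""
    return np.arange(lo, hi + 0.5 * step, step)


def band_epsilon(nu, nu_if: float, f: float, fwhm: float = DEFAULT_FWHM):
    """Gaussian band contribution to eps(nu') from a single excitation."""
    if not fwhm > 0:
        raise ValueError("fwhm must be positive")
    if f < 0:
        raise ValueError("oscillator strength must be >= 0")
    nu = np.asarray(nu, dtype=float)
    out = (BROADENING_PREFACTOR / fwhm) * f * np.exp(
        -BROADENING_EXPONENT * (nu - nu_if) ** 2 / fwhm**2
    )
    return out if out.ndim else float(out)


def convolve_spectrum(
    table: ExcitationTable,
    grid: np.ndarray | None = None,
    fwhm: float = DEFAULT_FWHM,
) -> Spectrum:
    """Sum of Gaussian bands over all excitations of a table.

    Warns if the grid does not cover every band to +-5 fwhm, where the
    Gaussian tails are no longer negligible for integrated quantities.
    """
    if len(table) == 0:
        raise ValueError("excitation table is empty")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    positions = np.array([e.position for e in table.excitations])
    if positions.min() - 5 * fwhm < grid[0] or positions.max() + 5 * fwhm > grid[-1]:
        import warnings

        warnings.warn(
            "grid does not cover all bands to +-5 FWHM; integrated "
            "quantities will be truncated", stacklevel=2,
        )
    eps = np.zeros_like(grid)
    for e in table.excitations:
        eps += band_epsilon(grid, e.position, e.f, fwhm)
    return Spectrum(grid=grid, epsilon=eps, fwhm=fwhm)


def dipole_from_f(f: float, position: float) -> float:
    """Transition dipole magnitude |M| (atomic units) from f and position.

    Uses the atomic-unit length-gauge identity f = (2/3) dE |M|^2 with dE
    in hartree; ``position`` is in cm^-1.
    """
    if f < 0:
        raise ValueError("oscillator strength must be >= 0")
    if not position > 0:
        raise ValueError("position must be positive")
    de_hartree = position / _CMINV_PER_HARTREE
    return math.sqrt(3.0 * f / (2.0 * de_hartree))


def f_from_dipole(m: float, position: float) -> float:
    """Inverse of :func:`dipole_from_f`: f = (2/3) dE |M|^2."""
    de_hartree = position / _CMINV_PER_HARTREE
    return (2.0 / 3.0) * de_hartree * m * m


@dataclass(frozen=True)
class EnsembleStats:
    """Snapshot-ensemble statistics of one absorption band."""

    mean_lambda_nm: float
    sigma_lambda_nm: float  # population standard deviation
    f_min: float
    f_max: float
    lambda_max_nm: tuple[float, ...]  # per snapshot


def ensemble_stats(
    tables: list[ExcitationTable],
    band_window: tuple[float, float],
    fwhm: float = DEFAULT_FWHM,
) -> EnsembleStats:
    """Band-maximum statistics over an ensemble of snapshot tables.

    ``band_window`` is (lambda_lo_nm, lambda_hi_nm) and must select at
    least one excitation in every snapshot; the per-snapshot band maximum
    is the peak of the convolved spectrum of the in-window excitations.
    Reports the population mean and standard deviation of lambda_max and
    the min/max in-window oscillator strength.
    """
    if len(tables) < 2:
        raise ValueError("ensemble statistics need at least 2 snapshots")
    lo_nm, hi_nm = sorted(band_window)
    lam_max = []
    f_all = []
    for k, table in enumerate(tables):
        selected = [e for e in table.excitations if lo_nm <= e.nm <= hi_nm]
        if not selected:
            name = table.label or f"snapshot {k}"
            raise ValueError(f"band window [{lo_nm}, {hi_nm}] nm selects no "
                             f"excitation in {name}")
        sub = ExcitationTable(tuple(selected), label=table.label)
        positions = [e.position for e in selected]
        grid = np.arange(min(positions) - 6 * fwhm, max(positions) + 6 * fwhm, 5.0)
        spec = convolve_spectrum(sub, grid, fwhm)
        lam_max.append(spec.lambda_max_nm)
        f_all.extend(e.f for e in selected)
    lam = np.array(lam_max)
    return EnsembleStats(
        mean_lambda_nm=float(lam.mean()),
        sigma_lambda_nm=float(lam.std()),  # population (ddof=0)
        f_min=float(min(f_all)),
        f_max=float(max(f_all)),
        lambda_max_nm=tuple(float(x) for x in lam),
    )


def molar_absorptivity(
    conc_abs_pairs: np.ndarray, path_cm: float = 1.0
) -> float:
    """Beer–Lambert molar absorptivity from (concentration M, absorbance).

    Zero-intercept least squares: eps = slope(A vs c) / path.
    """
    pairs = np.asarray(conc_abs_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise ValueError("need at least 3 (concentration, absorbance) pairs")
    if not path_cm > 0:
        raise ValueError("path length must be positive")
    c, A = pairs[:, 0], pairs[:, 1]
    denom = float(c @ c)
    if denom == 0:
        raise ValueError("all concentrations are zero")
    return float(c @ A) / denom / path_cm
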