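"""Host–guest equilibrium models and binding-constant fits.

Implements the 1:1 association isotherm used for direct fluorescence
titrations and the three-species competitive model behind indicator
displacement assays (IDA), where an analyte G displaces a reporter dye I
from a macrocyclic host H:

    H + I <-> HI   (K1)
    H + G <-> HG   (K2)

The 1:1 complex concentration is the smaller root of

    [HI]^2 - ([H]T + [I]T + 1/K1) [HI] + [H]T [I]T = 0,

and the competitive system is solved exactly from the mass balances as a
monotone scalar root-finding problem in the free host concentration.
Binding constants are estimated on a log10 scale with a linear
spectroscopic response model and residual-bootstrap uncertainty.

All concentrations are molar; binding constants are M^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "EquilibriumSystem",
    "SpeciesState",
    "TitrationSeries",
    "BindingFit",
    "ThermoRecord",
    "IdentifiabilityError",
    "ConvergenceError",
    "solve_1to1",
    "solve_competitive",
    "predict_signal",
    "fit_1to1",
    "fit_ida",
    "gibbs_from_k",
    "thermo_consistency",
    "GAS_CONSTANT_KCAL",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.98720425e-3


class IdentifiabilityError(ValueError):
    """The data carry no information on the requested parameter."""


class ConvergenceError(RuntimeError):
    """An iterative solver or optimizer failed to converge."""


@dataclass(frozen=True)
class EquilibriumSystem:
    """Total concentrations and association constants of an H/I/G mixture.

    ``G_total = 0`` reduces the system to a plain 1:1 titration.
    """

    H_total: float
    I_total: float
    G_total: float
    K1: float
    K2: float

    def __post_init__(self) -> None:
        for name in ("H_total", "I_total", "G_total"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("K1", "K2"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations of all five species (M)."""

    free_H: float
    free_I: float
    free_G: float
    HI: float
    HG: float

    def check_mass_balance(
        self, H_total: float, I_total: float, G_total: float, rtol: float = 1e-10
    ) -> None:
        """Raise if any of the three mass balances is violated."""
        for tot, got, label in (
            (H_total, self.free_H + self.HI + self.HG, "H"),
            (I_total, self.free_I + self.HI, "I"),
            (G_total, self.free_G + self.HG, "G"),
        ):
            if abs(got - tot) > rtol * max(tot, 1e-300):
                raise ValueError(f"{label} mass balance violated: {got} != {tot}")


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered titration: totals plus the observed signal at each point.

    ``mode`` distinguishes a direct host titration (host swept, indicator
    fixed) from a competitor titration (host and indicator fixed,
    competitor swept).
    """

    H_total: np.ndarray
    I_total: np.ndarray
    G_total: np.ndarray
    signal: np.ndarray
    mode: str  # "host_titration" | "competitor_titration"

    def __post_init__(self) -> None:
        for name in ("H_total", "I_total", "G_total", "signal"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.signal)
        if any(len(getattr(self, k)) != n for k in ("H_total", "I_total", "G_total")):
            raise ValueError("all columns must have equal length")
        if self.mode not in ("host_titration", "competitor_titration"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if np.any(self.H_total < 0) or np.any(self.I_total < 0) or np.any(self.G_total < 0):
            raise ValueError("totals must be non-negative")

    def __len__(self) -> int:
        return len(self.signal)


@dataclass(frozen=True)
class BindingFit:
    """Result of a binding-constant fit with bootstrap uncertainty."""

    K_hat: float
    signal_params: tuple[float, float]
    residual_norm: float
    K_interval: tuple[float, float]
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not self.K_hat > 0:
            raise ValueError("K_hat must be positive")
        lo, hi = self.K_interval
        if not (lo <= self.K_hat <= hi):
            raise ValueError("interval must contain K_hat")


@dataclass(frozen=True)
class ThermoRecord:
    """Binding thermodynamics in kcal/mol at temperature T (K).

    dG = dH - TdS must close to 0.05 kcal/mol when all three are set.
    """

    dG: float | None = None
    dH: float | None = None
    TdS: float | None = None
    T: float = 298.0

    def __post_init__(self) -> None:
        if None not in (self.dG, self.dH, self.TdS):
            if abs(self.dG - (self.dH - self.TdS)) > 0.05:
                raise ValueError("dG, dH and TdS are inconsistent beyond 0.05 kcal/mol")


# ---------------------------------------------------------------------------
# solvers


def solve_1to1(H_total: float, I_total: float, K1: float) -> SpeciesState:
    """Equilibrium speciation of a 1:1 host–indicator mixture.

    The complex concentration is the physically admissible (smaller) root
    of the association quadratic; the numerically stable citardauq form is
    used so weak binding does not lose precision to cancellation.
    K1 = +inf is accepted as the stoichiometric (infinitely tight) limit.
    """
    for name, v in (("H_total", H_total), ("I_total", I_total)):
        if math.isnan(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    if math.isnan(K1) or K1 < 0:
        raise ValueError(f"K1 must be >= 0, got {K1}")

    if K1 == 0:
        hi = 0.0
    elif math.isinf(K1):
        hi = min(H_total, I_total)
    else:
        b = H_total + I_total + 1.0 / K1
        c = H_total * I_total
        disc = b * b - 4.0 * c
        # disc >= (H-I)^2 + 1/K^2 > 0 always; guard rounding
        sq = math.sqrt(max(disc, 0.0))
        # smaller root via 2c / (b + sqrt) — stable for c << b^2
        hi = 2.0 * c / (b + sq)
    hi = min(hi, H_total, I_total)
    return SpeciesState(
        free_H=H_total - hi, free_I=I_total - hi, free_G=0.0, HI=hi, HG=0.0
    )


def _competitive_residual(h: float, sys: EquilibriumSystem) -> float:
    """Host mass-balance residual as a function of free host h (monotone)."""
    return (
        h
        + sys.K1 * h * sys.I_total / (1.0 + sys.K1 * h)
        + sys.K2 * h * sys.G_total / (1.0 + sys.K2 * h)
        - sys.H_total
    )


def solve_competitive(system: EquilibriumSystem) -> SpeciesState:
    """Exact speciation of the competitive H/I/G system.

    Eliminating free I and free G through their binding isotherms reduces
    the five coupled equations to one strictly increasing function of the
    free host concentration, bracketed on [0, H_total] and solved with
    Brent's method; every species then follows in closed form.

    Raises ConvergenceError if the bracketed solve fails (it cannot for
    valid finite inputs, but the residual is reported if it does).
    """
    if system.H_total == 0.0:
        return SpeciesState(0.0, system.I_total, system.G_total, 0.0, 0.0)
    lo, hi = 0.0, system.H_total
    try:
        h = optimize.brentq(
            _competitive_residual, lo, hi, args=(system,), xtol=1e-300, rtol=1e-15,
            maxiter=200,
        )
    except (ValueError, RuntimeError) as exc:  # pragma: no cover - defensive
        raise ConvergenceError(
            f"competitive solve failed: residual at brackets "
            f"{_competitive_residual(lo, system)!r}, "
            f"{_competitive_residual(hi, system)!r}"
        ) from exc
    free_I = system.I_total / (1.0 + system.K1 * h)
    free_G = system.G_total / (1.0 + system.K2 * h)
    HI = system.K1 * h * free_I
    HG = system.K2 * h * free_G
    # re-impose exact mass balance on the dependent species
    return SpeciesState(
        free_H=max(system.H_total - HI - HG, 0.0),
        free_I=system.I_total - HI,
        free_G=system.G_total - HG,
        HI=HI,
        HG=HG,
    )


def predict_signal(state: SpeciesState, signal_params: tuple[float, float]) -> float:
    """Linear spectroscopic response: I_free_coeff·[I] + I_complex_coeff·[HI]."""
    a, b = signal_params
    if not (np.isfinite(a) and np.isfinite(b)):
        raise ValueError("signal coefficients must be finite")
    return a * state.free_I + b * state.HI


# ---------------------------------------------------------------------------
# fitting


def _series_hi_free(logK: float, series: TitrationSeries, K1_fixed: float | None) -> tuple[np.ndarray, np.ndarray]:
    """free_I and HI columns at a trial log10 K over all titration points."""
    K = 10.0 ** logK
    free_i = np.empty(len(series))
    hi = np.empty(len(series))
    for j in range(len(series)):
        if K1_fixed is None:
            st = solve_1to1(series.H_total[j], series.I_total[j], K)
        else:
            st = solve_competitive(
                EquilibriumSystem(
                    series.H_total[j], series.I_total[j], series.G_total[j],
                    K1_fixed, K,
                )
            )
        free_i[j] = st.free_I
        hi[j] = st.HI
    return free_i, hi


def _profile_rss(
    logK: float,
    series: TitrationSeries,
    signal: np.ndarray,
    K1_fixed: float | None,
    complex_only: bool,
) -> tuple[float, tuple[float, float]]:
    """RSS with signal coefficients profiled out by linear least squares."""
    free_i, hi = _series_hi_free(logK, series, K1_fixed)
    if complex_only:
        X = hi[:, None]
    else:
        X = np.column_stack([free_i, hi])
    coef, *_ = np.linalg.lstsq(X, signal, rcond=None)
    resid = signal - X @ coef
    if complex_only:
        params = (0.0, float(coef[0]))
    else:
        params = (float(coef[0]), float(coef[1]))
    return float(resid @ resid), params


def _fit_logk(
    series: TitrationSeries,
    signal: np.ndarray,
    K1_fixed: float | None,
    complex_only: bool,
    starts: tuple[float, ...] = (3.0, 5.0, 7.0),
) -> tuple[float, tuple[float, float], float]:
    """Multi-start 1-D minimisation of the profiled RSS over log10 K."""
    best = None
    for s0 in starts:
        res = optimize.minimize_scalar(
            lambda lk: _profile_rss(lk, series, signal, K1_fixed, complex_only)[0],
            bounds=(max(s0 - 4.0, -2.0), min(s0 + 4.0, 12.0)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    # polish on the full admissible range around the winner
    res = optimize.minimize_scalar(
        lambda lk: _profile_rss(lk, series, signal, K1_fixed, complex_only)[0],
        bounds=(best.x - 1.0, best.x + 1.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    if res.fun <= best.fun:
        best = res
    rss, params = _profile_rss(best.x, series, signal, K1_fixed, complex_only)
    return float(best.x), params, rss


def _check_fittable(series: TitrationSeries, expected_mode: str) -> None:
    if series.mode != expected_mode:
        raise ValueError(f"series mode must be {expected_mode!r}, got {series.mode!r}")
    if len(series) < 4:
        raise ValueError("at least 4 titration points are required")
    span = np.ptp(series.signal)
    scale = max(abs(series.signal).max(), 1e-300)
    if span <= 1e-9 * scale:
        raise IdentifiabilityError(
            "signal is constant across the titration; K is not identifiable"
        )


def _bootstrap_interval(
    logk_hat: float,
    series: TitrationSeries,
    fitted: np.ndarray,
    K1_fixed: float | None,
    complex_only: bool,
    n_boot: int,
    seed: int,
) -> tuple[float, float]:
    """Percentile interval on K from residual resampling around the fit."""
    if n_boot == 0:
        k = 10.0 ** logk_hat
        return (k, k)
    rng = np.random.default_rng(seed)
    resid = series.signal - fitted
    draws = np.empty(n_boot)
    for b in range(n_boot):
        boot_sig = fitted + rng.choice(resid, size=len(resid), replace=True)
        lk, _, _ = _fit_logk(series, boot_sig, K1_fixed, complex_only,
                             starts=(logk_hat,))
        draws[b] = lk
    lo, hi = np.percentile(draws, [2.5, 97.5])
    # the interval must bracket the point estimate even for tiny residuals
    return float(min(10.0 ** lo, 10.0 ** logk_hat)), float(max(10.0 ** hi, 10.0 ** logk_hat))


def fit_1to1(
    series: TitrationSeries,
    n_boot: int = 500,
    seed: int = 0,
    complex_only: bool = False,
) -> BindingFit:
    """Fit the 1:1 association constant to a host-titration series.

    The optimiser works on log10 K (multi-start at 10^3, 10^5, 10^7 M^-1);
    the two linear response coefficients are profiled out exactly at each
    trial K. Uncertainty is a 95% residual-bootstrap percentile interval.
    ``complex_only=True`` drops the free-indicator term from the response.
    """
    _check_fittable(series, "host_titration")
    logk, params, rss = _fit_logk(series, series.signal, None, complex_only)
    free_i, hi = _series_hi_free(logk, series, None)
    fitted = params[0] * free_i + params[1] * hi
    interval = _bootstrap_interval(logk, series, fitted, None, complex_only, n_boot, seed)
    return BindingFit(
        K_hat=10.0 ** logk,
        signal_params=params,
        residual_norm=math.sqrt(rss),
        K_interval=interval,
        n_boot=n_boot,
        seed=seed,
    )


def fit_ida(
    series: TitrationSeries,
    K1_fixed: float,
    n_boot: int = 500,
    seed: int = 0,
    complex_only: bool = False,
) -> BindingFit:
    """Fit the competitor constant K2 to an indicator-displacement series.

    K1 (indicator·host) must be supplied, typically from ``fit_1to1`` on a
    direct titration; the displacement curve then identifies K2 through the
    exact competitive speciation at every point.
    """
    if not K1_fixed > 0:
        raise ValueError("K1_fixed must be positive")
    _check_fittable(series, "competitor_titration")
    logk, params, rss = _fit_logk(series, series.signal, K1_fixed, complex_only)
    free_i, hi = _series_hi_free(logk, series, K1_fixed)
    if np.ptp(hi) <= 1e-3 * max(abs(hi).max(), 1e-300):
        raise IdentifiabilityError(
            "competitor sweep leaves the complex concentration unchanged; "
            "K2 is not identifiable"
        )
    fitted = params[0] * free_i + params[1] * hi
    interval = _bootstrap_interval(logk, series, fitted, K1_fixed, complex_only, n_boot, seed)
    return BindingFit(
        K_hat=10.0 ** logk,
        signal_params=params,
        residual_norm=math.sqrt(rss),
        K_interval=interval,
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# thermodynamic bookkeeping


def gibbs_from_k(K: float, T: float = 298.0) -> float:
    """Standard binding free energy ΔG = −RT ln K in kcal/mol."""
    if not K > 0:
        raise ValueError(f"K must be positive, got {K}")
    if not T > 0:
        raise ValueError(f"T must be positive, got {T}")
    return -GAS_CONSTANT_KCAL * T * math.log(K)


def thermo_consistency(dH: float, TdS: float) -> float:
    """ΔG from its enthalpic and entropic parts: ΔG = ΔH − TΔS."""
    if not (np.isfinite(dH) and np.isfinite(TdS)):
        raise ValueError("dH and TdS must be finite")
    return dH - TdS
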