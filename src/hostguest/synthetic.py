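"""Seeded synthetic-data generators for every analysis stage.

Each generator is a pure function of its parameters and a mandatory seed,
producing data with exactly the statistical structure the corresponding
analysis assumes: 1:1 and competitive titration curves with multiplicative
Gaussian noise (the shot-dominated regime of a fluorimeter), Poisson
photon-counting decay traces smeared by a Gaussian instrument response,
thermally jittered excitation ensembles, and water boxes with planted
solvation-shell geometry.

Default regimes mirror a cucurbit[7]uril-type experiment: binding
constants near 5e5 M^-1, indicator around 1 uM, host swept over 0–90 uM,
competitor over 8–1500 uM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .equilibria import EquilibriumSystem, TitrationSeries, predict_signal, solve_1to1, solve_competitive
from .photophysics import DecayTrace, MultiExpModel, reconvolve
from .spectra import Excitation, ExcitationTable
from .solvation import ATOMIC_MASSES, Trajectory

__all__ = [
    "gen_titration",
    "gen_ida",
    "gen_decay",
    "gen_excitation_ensemble",
    "gen_solvation_frames",
    "PlantedWater",
    "SolvationScene",
    "default_host_sweep",
    "default_competitor_sweep",
]


def default_host_sweep(n: int = 16, lo: float = 0.0, hi: float = 90e-6) -> np.ndarray:
    """Host totals for a direct titration: 0–90 uM, in molar."""
    return np.linspace(lo, hi, n)


def default_competitor_sweep(n: int = 16, lo: float = 8e-6, hi: float = 1500e-6) -> np.ndarray:
    """Competitor totals for a displacement titration: 8–1500 uM (log-spaced)."""
    return np.geomspace(lo, hi, n)


def gen_titration(
    K: float = 4.54e5,
    H_totals: np.ndarray | None = None,
    I_total: float = 1e-6,
    signal_params: tuple[float, float] = (1e5, 1e6),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Direct 1:1 titration: indicator fixed, host swept.

    signal = predict_signal(solve_1to1(...)) * (1 + N(0, noise_sd)).
    """
    if not K > 0:
        raise ValueError("K must be positive")
    H = default_host_sweep() if H_totals is None else np.asarray(H_totals, dtype=float)
    if len(H) < 4:
        raise ValueError("need at least 4 host totals")
    rng = np.random.default_rng(seed)
    signal = np.array(
        [predict_signal(solve_1to1(h, I_total, K), signal_params) for h in H]
    )
    signal = signal * (1.0 + rng.normal(0.0, noise_sd, size=len(H))) if noise_sd > 0 else signal
    return TitrationSeries(
        H_total=H,
        I_total=np.full_like(H, I_total),
        G_total=np.zeros_like(H),
        signal=signal,
        mode="host_titration",
    )


def gen_ida(
    K1: float = 4.54e5,
    K2: float = 5.5e5,
    H_total: float = 10e-6,
    I_total: float = 0.5e-6,
    G_totals: np.ndarray | None = None,
    signal_params: tuple[float, float] = (1e5, 1e6),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Indicator displacement titration: host and indicator fixed, competitor swept."""
    if not K1 > 0 or K2 < 0:
        raise ValueError("K1 must be positive and K2 non-negative")
    G = default_competitor_sweep() if G_totals is None else np.asarray(G_totals, dtype=float)
    if len(G) < 4:
        raise ValueError("need at least 4 competitor totals")
    rng = np.random.default_rng(seed)
    signal = np.empty(len(G))
    for j, g in enumerate(G):
        st = solve_competitive(EquilibriumSystem(H_total, I_total, g, K1, K2))
        signal[j] = predict_signal(st, signal_params)
    if noise_sd > 0:
        signal = signal * (1.0 + rng.normal(0.0, noise_sd, size=len(G)))
    return TitrationSeries(
        H_total=np.full_like(G, H_total),
        I_total=np.full_like(G, I_total),
        G_total=G,
        signal=signal,
        mode="competitor_titration",
    )


def gen_decay(
    lifetimes: tuple[float, ...] = (4.87,),
    fractions: tuple[float, ...] = (1.0,),
    irf_fwhm: float = 0.2,
    peak_counts: float = 10_000.0,
    bin_width: float = 0.025,
    n_bins: int = 1600,
    seed: int = 0,
    expectation: bool = False,
) -> DecayTrace:
    """Synthetic TCSPC acquisition: Poisson counts around a reconvolved decay.

    ``fractions`` are fractional intensities f_i = a_i tau_i / sum (they
    must sum to 1); amplitudes follow as a_i ~ f_i / tau_i. The IRF is a
    Gaussian of the given FWHM placed early in the window; the expectation
    curve is scaled so its maximum equals ``peak_counts`` before Poisson
    sampling. ``expectation=True`` skips the sampling (infinite-count
    limit).
    """
    lifetimes = tuple(float(t) for t in lifetimes)
    fractions = tuple(float(f) for f in fractions)
    if len(lifetimes) != len(fractions):
        raise ValueError("lifetimes and fractions must align")
    if any(t <= 0 for t in lifetimes):
        raise ValueError("lifetimes must be positive")
    if abs(sum(fractions) - 1.0) > 1e-9 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    edges = np.arange(n_bins + 1) * bin_width
    t = 0.5 * (edges[:-1] + edges[1:])
    sigma = irf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t0 = max(5.0 * sigma, 10 * bin_width)
    irf = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    irf_hist = irf / irf.max() * peak_counts  # recorded like a measured IRF
    amps = np.array([f / tau for f, tau in zip(fractions, lifetimes)])
    model = MultiExpModel(amplitudes=tuple(amps), lifetimes=lifetimes)
    expected = reconvolve(model, irf_hist, edges)
    expected *= peak_counts / expected.max()
    counts = expected if expectation else rng.poisson(expected).astype(float)
    return DecayTrace(bin_edges=edges, counts=counts, irf_counts=irf_hist)


def gen_excitation_ensemble(
    base_table: ExcitationTable,
    sigma_lambda: float = 6.0,
    sigma_f: float = 0.0,
    n_snapshots: int = 10,
    seed: int = 0,
) -> list[ExcitationTable]:
    """Thermally jittered copies of an excitation table.

    Positions are jittered in the wavelength (nm) domain, oscillator
    strengths in place with a floor at zero — mimicking snapshot-to-
    snapshot solvation shifts of an MD-sampled chromophore.
    """
    if sigma_lambda < 0 or sigma_f < 0:
        raise ValueError("sigmas must be >= 0")
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_snapshots):
        exc = []
        for e in base_table.excitations:
            nm = e.nm + (rng.normal(0.0, sigma_lambda) if sigma_lambda > 0 else 0.0)
            nm = max(nm, 1e-3)
            f = e.f + (rng.normal(0.0, sigma_f) if sigma_f > 0 else 0.0)
            exc.append(Excitation.from_nm(nm, max(f, 0.0)))
        out.append(ExcitationTable(tuple(exc), label=f"snapshot-{k}"))
    return out


# ---------------------------------------------------------------------------
# solvation scenes


@dataclass(frozen=True)
class PlantedWater:
    """Prescribed water placement relative to the solute donor axis.

    ``distance``: solute-N to water-O distance (A); ``angle_deg``: angle at
    the solute donor between the N-H axis and N->O (0 = on-axis, i.e. a
    geometry that satisfies the H-bond criterion when close enough);
    ``azimuth_deg`` disambiguates the direction around the axis.
    """

    distance: float
    angle_deg: float = 0.0
    azimuth_deg: float = 0.0


@dataclass(frozen=True)
class SolvationScene:
    """A generated trajectory plus the bookkeeping its analysis needs."""

    trajectory: Trajectory
    solute_indices: np.ndarray  # N and H
    solute_donor: int  # N index
    solute_hydrogen: int  # H index
    water_groups: tuple[tuple[int, int, int], ...]  # (O, H, H) per water
    planted: tuple[tuple[int, int, int], ...]  # the planted subset


_OH = 0.9572  # A
_HOH = math.radians(104.52)


def _water_atoms(o_pos: np.ndarray, toward: np.ndarray, rng) -> np.ndarray:
    """O and two H coordinates for a water with its bisector along ``toward``."""
    z = toward / np.linalg.norm(toward)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, ref)
    x /= np.linalg.norm(x)
    half = _HOH / 2.0
    h1 = o_pos + _OH * (math.cos(half) * z + math.sin(half) * x)
    h2 = o_pos + _OH * (math.cos(half) * z - math.sin(half) * x)
    return np.vstack([o_pos, h1, h2])


def gen_solvation_frames(
    n_waters: int = 50,
    box: float | np.ndarray = 24.0,
    planted_shell: tuple[PlantedWater, ...] = (),
    n_frames: int = 5,
    seed: int = 0,
    jitter: float = 0.02,
    min_separation: float = 2.5,
) -> SolvationScene:
    """Water box with a central N-H solute and a planted first shell.

    Planted waters sit at prescribed distance/angle from the solute donor
    (oxygen toward the solute, so an on-axis water within 3.5 A accepts a
    solute N-H hydrogen bond); the remaining waters are placed uniformly
    with overlap rejection at ``min_separation`` A. Frames differ by a
    small Gaussian jitter of all coordinates. Raises if the box cannot
    accommodate the requested count.
    """
    box = np.asarray([box] * 3 if np.isscalar(box) else box, dtype=float)
    rng = np.random.default_rng(seed)
    if len(planted_shell) > n_waters:
        raise ValueError("more planted waters than waters")
    center = box / 2.0
    axis = np.array([0.0, 0.0, 1.0])
    n_pos = center
    h_pos = center + 1.0 * axis  # N-H ~ 1.0 A

    coords = [n_pos, h_pos]
    labels = ["N", "H"]
    groups: list[tuple[int, int, int]] = []
    planted_groups: list[tuple[int, int, int]] = []

    def add_water(atoms: np.ndarray, planted: bool) -> None:
        i0 = len(coords)
        coords.extend(atoms)
        labels.extend(["O", "H", "H"])
        groups.append((i0, i0 + 1, i0 + 2))
        if planted:
            planted_groups.append((i0, i0 + 1, i0 + 2))

    for pw in planted_shell:
        th = math.radians(pw.angle_deg)
        ph = math.radians(pw.azimuth_deg)
        direction = np.array(
            [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
        )
        o_pos = n_pos + pw.distance * direction
        # bisector pointing away from the solute: O lone pair faces the donor
        add_water(_water_atoms(o_pos, direction, rng), planted=True)

    occupied = np.array(coords)
    attempts = 0
    while len(groups) < n_waters:
        attempts += 1
        if attempts > 20_000:
            raise RuntimeError(
                f"could not pack {n_waters} waters at >= {min_separation} A "
                f"into a {box} A box"
            )
        o_pos = rng.uniform(0.0, 1.0, size=3) * box
        d = occupied - o_pos
        d -= box * np.round(d / box)
        if np.min(np.linalg.norm(d, axis=1)) < min_separation:
            continue
        # keep bulk waters out of the planted first-shell region
        if np.linalg.norm(o_pos - n_pos) < 4.0:
            continue
        direction = rng.normal(size=3)
        atoms = _water_atoms(o_pos, direction, rng)
        add_water(atoms, planted=False)
        occupied = np.array(coords)

    base = np.array(coords)
    frames = np.array(
        [base + rng.normal(0.0, jitter, size=base.shape) for _ in range(n_frames)]
    )
    traj = Trajectory(labels=tuple(labels), frames=frames, box=box)
    return SolvationScene(
        trajectory=traj,
        solute_indices=np.array([0, 1]),
        solute_donor=0,
        solute_hydrogen=1,
        water_groups=tuple(groups),
        planted=tuple(planted_groups),
    )
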