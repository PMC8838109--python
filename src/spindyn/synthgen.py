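"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the raw observables of a variable-temperature
solid-state NMR + DSC study of a small-molecule molecular crystal:

* mono-exponential magnetization decays (T1 / T1rho experiments),
* Arrhenius rate series on the fast or slow side of the relaxation
  maximum,
* axially symmetric (eta = 0) dipolar powder patterns, optionally
  pre-scaled by the Lee-Goldburg factor,
* two-site exchange lineshapes across coalescence,
* DSC traces with lambda-shaped transitions and baseline cp steps,
* toy unit cells of hard spheres for the crystal-geometry stage.

Every generator takes an explicit seed and is bit-reproducible; noise
defaults are fixture choices (2 percent relative), not calibrated to
any instrument.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .constants import R_GAS, SIMVASTATIN_MOLAR_MASS, BONDI_RADII
from .exceptions import CoverageError, InvalidParameterError
from .relax import DecayCurve, RateSeries
from .dipolar import DipolarPattern
from .thermo import DSCTrace
from .xtalgeom import Site, UnitCell

__all__ = [
    "GroundTruth",
    "ExchangePair",
    "Spectrum",
    "gen_decay",
    "gen_rate_series",
    "gen_pake",
    "gen_exchange_spectrum",
    "gen_dsc",
    "gen_toy_cell",
    "write_curve_csv",
    "write_ground_truth",
    "write_cif",
]


@dataclass(frozen=True)
class GroundTruth:
    """Arrhenius ground truth: rate = A * exp(+-E*/RT).

    e_star in kJ/mol, a (prefactor) in 1/s, noise_sd is the relative
    Gaussian noise level.
    """

    e_star: float
    a: float = 1.0
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.e_star < 0:
            raise InvalidParameterError("activation energy must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if self.a <= 0:
            raise InvalidParameterError("prefactor must be > 0")


@dataclass(frozen=True)
class ExchangePair:
    """Two exchanging resonances: frequencies in Hz, rate k in 1/s."""

    nu_a: float
    nu_b: float
    k: float
    t2: float = 1.0
    populations: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self):
        if self.k < 0:
            raise InvalidParameterError("exchange rate must be >= 0")
        if self.t2 <= 0:
            raise InvalidParameterError("T2 must be > 0")
        if abs(sum(self.populations) - 1.0) > 1e-9 or min(self.populations) < 0:
            raise InvalidParameterError("populations must be non-negative and sum to 1")


@dataclass(frozen=True)
class Spectrum:
    freqs: np.ndarray  # Hz
    intensities: np.ndarray


def gen_decay(
    t1_true: float,
    delays,
    noise_sd: float = 0.0,
    seed: int | None = None,
    site: str = "",
    frame: str = "lab",
    spin_lock_nu: float | None = None,
    stretch_beta: float | None = None,
) -> DecayCurve:
    """Mono-exponential decay I(t) = exp(-t/T1) * (1 + eps), eps ~ N(0, noise_sd).

    `stretch_beta` switches to a stretched exponential exp(-(t/T1)^beta);
    default off.
    """
    if t1_true <= 0:
        raise InvalidParameterError("T1 must be positive")
    delays = np.asarray(delays, dtype=float)
    if delays.size == 0 or np.any(delays < 0):
        raise InvalidParameterError("delays must be non-empty and non-negative")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    x = delays / t1_true
    inten = np.exp(-(x**stretch_beta)) if stretch_beta else np.exp(-x)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inten = inten * (1.0 + noise_sd * rng.standard_normal(inten.shape))
    return DecayCurve(
        delays=delays, intensities=inten, site=site, frame=frame,
        spin_lock_nu=spin_lock_nu, meta={"t1_true": t1_true, "noise_sd": noise_sd, "seed": seed},
    )


def gen_rate_series(
    truth: GroundTruth,
    temperatures,
    branch: str = "slow",
    site: str = "",
    frame: str = "lab",
    spin_lock_nu: float | None = None,
) -> RateSeries:
    """Arrhenius rate series R = A * exp(+E*/RT) (slow) or A * exp(-E*/RT) (fast).

    The slow branch follows the printed convention for rates that rise as
    the temperature falls; ln R vs 1/T is exactly linear at zero noise.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if temperatures.size == 0:
        raise InvalidParameterError("temperature list must be non-empty")
    if np.any(temperatures <= 0):
        raise InvalidParameterError("temperatures must be positive (K)")
    if branch not in ("fast", "slow"):
        raise InvalidParameterError("branch must be 'fast' or 'slow'")
    sign = +1.0 if branch == "slow" else -1.0
    rates = truth.a * np.exp(sign * truth.e_star * 1e3 / (R_GAS * temperatures))
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        rates = rates * (1.0 + truth.noise_sd * rng.standard_normal(rates.shape))
        rates = np.abs(rates)  # rates stay positive
    return RateSeries(
        temperatures=temperatures, rates=rates, site=site, frame=frame,
        spin_lock_nu=spin_lock_nu,
        meta={"e_star_true": truth.e_star, "a_true": truth.a, "branch": branch,
              "noise_sd": truth.noise_sd, "seed": truth.seed},
    )


def _pake_bin_mass(delta: float, bin_edges: np.ndarray) -> np.ndarray:
    """Exact per-bin mass of the eta=0 powder doublet with horn splitting delta.

    Each branch has single-crystal frequency nu(u) = (delta/2)(3u^2 - 1)
    with u = cos(theta) uniform on [0, 1]; the per-bin mass is a CDF
    difference, so the edge singularities at +-delta/2 are integrated
    exactly rather than sampled.
    """
    def cdf(nu):
        x = np.clip((2.0 * nu / delta + 1.0) / 3.0, 0.0, 1.0)
        return np.sqrt(x)

    m_plus = cdf(bin_edges[1:]) - cdf(bin_edges[:-1])
    m_minus = cdf(-bin_edges[:-1]) - cdf(-bin_edges[1:])
    return 0.5 * (m_plus + m_minus)


def gen_pake(
    d_coupling: float,
    scale: float = 1.0,
    lb: float = 0.1,
    grid=None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    site: str = "",
) -> DipolarPattern:
    """Axially symmetric dipolar powder pattern (Pake doublet).

    Parameters
    ----------
    d_coupling : effective dipolar coupling D in kHz. The horn-to-horn
        splitting of the noiseless pattern equals ``scale * d_coupling``.
    scale : scaling factor already applied to the data (e.g. the
        Lee-Goldburg factor 1/sqrt(3)); recorded as ``scale_applied``.
    lb : Gaussian line broadening (FWHM, kHz).
    grid : frequency axis in kHz; must cover +-scale*D (the full pattern
        spans +-scale*D including the outer shoulders). Default: +-1.4
        scale*D at 0.1 kHz spacing.
    """
    if d_coupling <= 0:
        raise InvalidParameterError("coupling must be positive")
    if not 0.0 < scale <= 1.0:
        raise InvalidParameterError("scale must be in (0, 1]")
    delta = scale * d_coupling
    if grid is None:
        span = 1.4 * delta
        grid = np.arange(-span, span + 0.05, 0.1)
    grid = np.asarray(grid, dtype=float)
    if grid[0] > -delta or grid[-1] < delta:
        raise CoverageError(
            f"grid [{grid[0]:.2f}, {grid[-1]:.2f}] kHz does not cover the "
            f"pattern extent +-{delta:.2f} kHz"
        )
    db = grid[1] - grid[0]
    edges = np.append(grid - db / 2.0, grid[-1] + db / 2.0)
    y = _pake_bin_mass(delta, edges)
    if lb > 0:
        sig = lb / 2.3548200450309493
        half = np.arange(0.0, 6.0 * sig + db, db)
        kern_x = np.concatenate([-half[:0:-1], half])
        kern = np.exp(-0.5 * (kern_x / sig) ** 2)
        kern /= kern.sum()
        y = np.convolve(y, kern, mode="same")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + noise_sd * y.max() * rng.standard_normal(y.shape)
    return DipolarPattern(
        freqs=grid, intensities=y, site=site, scale_applied=scale,
        meta={"d_true": d_coupling, "lb": lb, "noise_sd": noise_sd, "seed": seed},
    )


def gen_exchange_spectrum(pair: ExchangePair, grid) -> Spectrum:
    """Two-site Bloch-McConnell exchange lineshape (emulation, not a paper formula).

    Rate constants are k_ab = 2 k p_b and k_ba = 2 k p_a, so for equal
    populations k is the per-site jump rate and the classical coalescence
    condition k = pi * dnu / sqrt(2) holds. The k -> 0 limit gives two
    Lorentzians at nu_a and nu_b; k -> inf a single Lorentzian at the
    population-weighted mean.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = min(pair.nu_a, pair.nu_b), max(pair.nu_a, pair.nu_b)
    if grid[0] > lo or grid[-1] < hi:
        raise CoverageError("grid must span both site frequencies")
    p_a, p_b = pair.populations
    k_ab = 2.0 * pair.k * p_b
    k_ba = 2.0 * pair.k * p_a
    r2 = 1.0 / pair.t2
    alpha_a = 1j * 2.0 * np.pi * (grid - pair.nu_a) + r2 + k_ab
    alpha_b = 1j * 2.0 * np.pi * (grid - pair.nu_b) + r2 + k_ba
    det = alpha_a * alpha_b - k_ab * k_ba
    total = (p_a * (alpha_b + k_ab) + p_b * (alpha_a + k_ba)) / det
    return Spectrum(freqs=grid, intensities=total.real)


def _lambda_peak(t: np.ndarray, t_c: float, width: float) -> np.ndarray:
    """Asymmetric lambda-shaped excess-cp peak, unit area (fixture shape).

    Power-law rise over ~4 widths below t_c, sharp Gaussian cut above.
    Only the integral is contractually meaningful.
    """
    y = np.zeros_like(t)
    rise = (t > t_c - 4.0 * width) & (t <= t_c)
    x = (t[rise] - (t_c - 4.0 * width)) / (4.0 * width)
    y[rise] = x**3
    fall = t > t_c
    y[fall] = np.exp(-0.5 * ((t[fall] - t_c) / (width / 4.0)) ** 2)
    area = np.trapezoid(y, t)
    return y / area if area > 0 else y


def gen_dsc(
    baseline_cp,
    transitions=(),
    t_range: tuple[float, float] = (200.0, 320.0),
    step: float = 0.02,
    scan_rate: float = 10.0,
    mode: str = "cp",
    molar_mass: float = SIMVASTATIN_MOLAR_MASS,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DSCTrace:
    """Synthetic DSC trace: piecewise baseline cp plus lambda transitions.

    Parameters
    ----------
    baseline_cp : scalar cp in J/(g K), or a sequence of (T_onset, cp)
        pairs defining a piecewise-constant baseline (steps at T_onset).
    transitions : iterable of (T_c K, dH kJ/mol, width K).
    mode : 'cp' emits specific heat in J/(g K); 'heatflow' emits
        heat flow in W/g (cp times the scan rate).
    scan_rate : K/min, recorded on the trace (sign gives direction).
    """
    t = np.arange(t_range[0], t_range[1] + step / 2, step)
    if np.isscalar(baseline_cp):
        cp = np.full_like(t, float(baseline_cp))
    else:
        pieces = sorted(baseline_cp)
        cp = np.full_like(t, pieces[0][1])
        for t_on, val in pieces:
            cp[t >= t_on] = val
    transitions = list(transitions)
    for i in range(len(transitions)):
        for j in range(i + 1, len(transitions)):
            if abs(transitions[i][0] - transitions[j][0]) < 3 * max(
                transitions[i][2], transitions[j][2]
            ):
                warnings.warn(
                    "transitions closer than 3 widths overlap; integrals may mix",
                    stacklevel=2,
                )
    for t_c, dh_kj_mol, width in transitions:
        if width <= 0:
            raise InvalidParameterError("transition width must be positive")
        dh_specific = dh_kj_mol * 1e3 / molar_mass  # J/g
        cp = cp + dh_specific * _lambda_peak(t, t_c, width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp + noise_sd * rng.standard_normal(cp.shape)
    if mode == "cp":
        signal = cp
    elif mode == "heatflow":
        signal = cp * scan_rate / 60.0  # W/g
    else:
        raise InvalidParameterError("mode must be 'cp' or 'heatflow'")
    return DSCTrace(
        temperatures=t, signal=signal, mode=mode, scan_rate=scan_rate,
        meta={"transitions": transitions, "noise_sd": noise_sd, "seed": seed,
              "molar_mass": molar_mass},
    )


def gen_toy_cell(lattice, sites) -> UnitCell:
    """Toy unit cell of hard spheres.

    lattice: (a, b, c, alpha, beta, gamma); sites: iterable of
    (element, (x, y, z) fractional[, label]). Elements must be in the
    Bondi radii table so the geometry stage can use them.
    """
    a, b, c, alpha, beta, gamma = lattice
    out = []
    for i, entry in enumerate(sites):
        element, frac = entry[0], entry[1]
        label = entry[2] if len(entry) > 2 else f"{element}{i + 1}"
        if element not in BONDI_RADII:
            raise KeyError(f"unknown element symbol {element!r}")
        out.append(Site(element, tuple(float(x) for x in frac), label))
    return UnitCell(a, b, c, alpha, beta, gamma, tuple(out))


# ---------------------------------------------------------------- writers

def write_curve_csv(obj, path) -> None:
    """Write a decay curve, rate series, spectrum or DSC trace as CSV."""
    if isinstance(obj, DecayCurve):
        df = pd.DataFrame({"delay_s": obj.delays, "intensity": obj.intensities})
    elif isinstance(obj, RateSeries):
        df = pd.DataFrame(
            {"site": obj.site, "T_K": obj.temperatures, "rate_s-1": obj.rates,
             "frame": obj.frame, "spin_lock_kHz": obj.spin_lock_nu}
        )
    elif isinstance(obj, DipolarPattern):
        df = pd.DataFrame({"freq_kHz": obj.freqs, "intensity": obj.intensities})
    elif isinstance(obj, DSCTrace):
        df = pd.DataFrame({"T_K": obj.temperatures, "signal": obj.signal})
    elif isinstance(obj, Spectrum):
        df = pd.DataFrame({"freq_Hz": obj.freqs, "intensity": obj.intensities})
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    df.to_csv(path, index=False)


def write_ground_truth(meta: dict, path) -> None:
    """JSON sidecar with the generating parameters."""
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1, default=float)


def write_cif(cell: UnitCell, path, data_name: str = "toy") -> None:
    """Minimal P1 CIF writer for toy cells."""
    lines = [
        f"data_{data_name}",
        f"_cell_length_a {cell.a:.6f}",
        f"_cell_length_b {cell.b:.6f}",
        f"_cell_length_c {cell.c:.6f}",
        f"_cell_angle_alpha {cell.alpha:.4f}",
        f"_cell_angle_beta {cell.beta:.4f}",
        f"_cell_angle_gamma {cell.gamma:.4f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for s in cell.sites:
        x, y, z = s.frac
        lines.append(f"{s.label} {s.element} {x:.6f} {y:.6f} {z:.6f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
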