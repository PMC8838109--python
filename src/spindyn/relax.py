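"""Spin-relaxation analysis: T1/T1rho estimation, Arrhenius activation
energies, and BPP spectral-density modelling.

Variable-temperature T1 (laboratory frame, sensitive to ~100 MHz motion)
and T1rho (rotating frame, ~10-100 kHz motion) series are reduced in
three steps: (i) a mono-exponential fit of each magnetization decay,
(ii) an ordinary least-squares fit of ln(rate) against inverse
temperature, whose slope gives the activation energy E* of the segmental
motion, and (iii) inversion of the heteronuclear dipolar BPP expression
to a motional correlation time tau_c on the fast or slow side of the
relaxation maximum.

Sign convention: a *slow*-branch series has rates rising as the
temperature falls (rate = A exp(+E*/RT), correlation frequency below the
probe frequency); a *fast*-branch series has rate = A exp(-E*/RT).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .constants import (
    GAMMA_C, GAMMA_H, HBAR, MU0_OVER_4PI, NU_C_DEFAULT_MHZ, NU_H_DEFAULT_MHZ, R_GAS,
)
from .exceptions import FitError, InvalidParameterError, NoSolutionError, WindowError

__all__ = [
    "DecayCurve",
    "RateSeries",
    "ArrheniusResult",
    "SpectralDensityParams",
    "ExponentialDecayModel",
    "DecayFitResults",
    "ArrheniusModel",
    "fit_decay",
    "arrhenius_fit",
    "bpp_rate",
    "bpp_max",
    "invert_rate_to_tau",
    "r1rho_max_tau",
    "classify_branch",
]


@dataclass(frozen=True)
class DecayCurve:
    """A magnetization decay: intensity vs delay for one site."""

    delays: np.ndarray  # s, strictly increasing for fitting
    intensities: np.ndarray
    site: str = ""
    frame: str = "lab"  # lab | rotating
    spin_lock_nu: float | None = None  # kHz, rotating frame only
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RateSeries:
    """Per-site relaxation rates vs temperature."""

    temperatures: np.ndarray  # K
    rates: np.ndarray  # 1/s
    site: str = ""
    frame: str = "lab"
    spin_lock_nu: float | None = None  # kHz
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        r = np.asarray(self.rates, dtype=float)
        if t.shape != r.shape:
            raise InvalidParameterError("temperatures and rates must have equal length")
        if np.any(t <= 0) or np.any(r <= 0):
            raise InvalidParameterError("temperatures and rates must be positive")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "rates", r)


@dataclass(frozen=True)
class ArrheniusResult:
    """Activation energy from ln(rate) vs 1/T.

    e_star in kJ/mol; branch 'slow' if the slope of ln R vs 1/T is
    positive (rates rise on cooling), 'fast' otherwise.
    """

    e_star: float
    ln_a: float
    branch: str
    stderr_e: float
    r_squared: float
    n: int
    flat: bool = False  # set when rates are constant and E* = 0 by convention

    def summary(self) -> str:
        lines = [
            "Arrhenius fit (ln R vs 1/T, OLS)",
            f"  n points    : {self.n}",
            f"  E*          : {self.e_star:.3f} +/- {self.stderr_e:.3f} kJ/mol",
            f"  ln A        : {self.ln_a:.3f}",
            f"  branch      : {self.branch}",
            f"  R-squared   : {self.r_squared:.5f}" + ("  (flat series)" if self.flat else ""),
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class SpectralDensityParams:
    """Inputs of the heteronuclear dipolar BPP rate.

    tau_c in s; r_ch in Angstrom; Larmor frequencies in MHz.
    geometry_factor is a dimensionless multiplier on the single-pair
    prefactor (3/20)(mu0/4pi)^2 hbar^2 gH^2 gC^2 / r^6 encoding the
    motional-model convention; the default 0.75 is the three-site methyl
    jump convention adopted here (see docs/methods.md) and is fully
    overridable.
    """

    tau_c: float = 1e-10
    r_ch: float = 1.09
    nu_c: float = NU_C_DEFAULT_MHZ
    nu_h: float = NU_H_DEFAULT_MHZ
    geometry_factor: float = 0.75

    def __post_init__(self):
        if min(self.tau_c, self.r_ch, self.nu_c, self.nu_h, self.geometry_factor) <= 0:
            raise InvalidParameterError("all spectral-density parameters must be positive")

    @property
    def prefactor(self) -> float:
        """geometry_factor * (3/20) (mu0/4pi)^2 hbar^2 gH^2 gC^2 / r^6, in s^-2."""
        d = MU0_OVER_4PI * HBAR * GAMMA_H * GAMMA_C / (self.r_ch * 1e-10) ** 3
        return self.geometry_factor * 0.15 * d * d


# ------------------------------------------------------------- decay fits

class ExponentialDecayModel:
    """Mono-exponential decay model I(t) = I0 exp(-t/T1).

    Statsmodels-style: construct from data, then ``fit()`` returns a
    :class:`DecayFitResults` carrying the estimate, its standard error
    and residual diagnostics.
    """

    def __init__(self, delays, intensities, site: str = ""):
        delays = np.asarray(delays, dtype=float)
        intensities = np.asarray(intensities, dtype=float)
        if delays.ndim != 1 or delays.shape != intensities.shape:
            raise InvalidParameterError("delays and intensities must be 1-D and equal length")
        if np.any(np.diff(delays) <= 0):
            raise InvalidParameterError("delays must be strictly increasing")
        self.delays = delays
        self.intensities = intensities
        self.site = site

    @classmethod
    def from_curve(cls, curve: DecayCurve) -> "ExponentialDecayModel":
        return cls(curve.delays, curve.intensities, site=curve.site)

    def fit(self) -> "DecayFitResults":
        t, y = self.delays, self.intensities
        if np.ptp(y) == 0:
            raise InvalidParameterError("intensities are constant; nothing to fit")
        if len(t) == 2 and y[0] > 0 and y[1] > 0 and y[1] < y[0]:
            # exact two-point solution (degenerate but well posed)
            t1 = (t[1] - t[0]) / math.log(y[0] / y[1])
            i0 = y[0] * math.exp(t[0] / t1)
            return DecayFitResults(self, t1, float("nan"), i0, float("nan"),
                                   y - i0 * np.exp(-t / t1))
        if len(t) < 4:
            warnings.warn("fewer than 4 points; decay fit is poorly determined",
                          stacklevel=2)
        # log-linear starting values on the positive part of the decay
        pos = y > 0
        slope = -1.0
        if pos.sum() >= 2:
            slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        t1_0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
        try:
            popt, pcov = optimize.curve_fit(
                lambda tt, i0, t1: i0 * np.exp(-tt / t1),
                t, y, p0=[max(y.max(), 1e-12), max(t1_0, 1e-12)], maxfev=10000,
            )
        except RuntimeError as exc:
            raise FitError(f"decay fit did not converge: {exc}",
                           residuals=y - y.mean()) from exc
        i0, t1 = popt
        if t1 <= 0 or not np.isfinite(t1):
            raise FitError("decay fit converged to a non-physical T1",
                           residuals=y - i0 * np.exp(-t / t1))
        perr = np.sqrt(np.diag(pcov))
        resid = y - i0 * np.exp(-t / t1)
        return DecayFitResults(self, float(t1), float(perr[1]), float(i0),
                               float(perr[0]), resid)


@dataclass(frozen=True)
class DecayFitResults:
    model: ExponentialDecayModel
    t1: float
    t1_stderr: float
    i0: float
    i0_stderr: float
    residuals: np.ndarray

    def summary(self) -> str:
        rms = float(np.sqrt(np.mean(self.residuals**2)))
        return "\n".join([
            "Mono-exponential decay fit",
            f"  site        : {self.model.site or '-'}",
            f"  n points    : {len(self.model.delays)}",
            f"  T1          : {self.t1:.6g} +/- {self.t1_stderr:.2g} s",
            f"  I0          : {self.i0:.6g}",
            f"  RMS residual: {rms:.3g}",
        ])

    def plot(self, ax=None):
        """Data and fitted decay on a linear-log axis (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.delays
        ax.plot(t, self.model.intensities, "o", label="data")
        tt = np.linspace(t[0], t[-1], 200)
        ax.plot(tt, self.i0 * np.exp(-tt / self.t1), "-",
                label=f"T1 = {self.t1:.3g} s")
        ax.set_xlabel("delay (s)")
        ax.set_ylabel("intensity")
        ax.legend()
        return ax


def fit_decay(curve: DecayCurve) -> tuple[float, float]:
    """T1 (s) and its standard error from a decay curve."""
    res = ExponentialDecayModel.from_curve(curve).fit()
    return res.t1, res.t1_stderr


# --------------------------------------------------------- Arrhenius fits

class ArrheniusModel:
    """ln(rate) vs 1/T linear model for activation energies.

    ``fit(window=(lo, hi))`` restricts the fit to a temperature window;
    a window containing the ∧-shaped relaxation maximum triggers a
    warning advising split windows.
    """

    def __init__(self, temperatures, rates, site: str = ""):
        self.series = RateSeries(np.asarray(temperatures, float),
                                 np.asarray(rates, float), site=site)

    @classmethod
    def from_series(cls, series: RateSeries) -> "ArrheniusModel":
        m = cls.__new__(cls)
        m.series = series
        return m

    @classmethod
    def from_dataframe(cls, df, site=None) -> "ArrheniusModel":
        """Build from a rate table with columns T_K and rate_s-1 (optionally site)."""
        if site is not None and "site" in df.columns:
            df = df[df["site"] == site]
        return cls(df["T_K"].to_numpy(), df["rate_s-1"].to_numpy(),
                   site=site or "")

    def fit(self, window: tuple[float, float] | None = None) -> ArrheniusResult:
        t = self.series.temperatures
        r = self.series.rates
        if window is not None:
            lo, hi = min(window), max(window)
            keep = (t >= lo) & (t <= hi)
            t, r = t[keep], r[keep]
        if len(t) < 3:
            raise WindowError("need at least 3 points in the fit window")
        order = np.argsort(t)
        t, r = t[order], r[order]
        ln_r = np.log(r)
        # warn if the window straddles a rate maximum (∧ shape in ln R vs 1/T)
        if len(t) >= 4:
            imax = int(np.argmax(ln_r))
            if 0 < imax < len(t) - 1:
                rise_left = ln_r[imax] - ln_r[0]
                rise_right = ln_r[imax] - ln_r[-1]
                if min(rise_left, rise_right) > 0.2:
                    warnings.warn(
                        "window contains a relaxation-rate maximum; fit the fast and "
                        "slow branches in separate windows", stacklevel=2,
                    )
        x = 1.0 / t
        if np.ptp(ln_r) == 0:
            return ArrheniusResult(0.0, float(ln_r[0]), "fast", 0.0, 0.0,
                                   len(t), flat=True)
        res = stats.linregress(x, ln_r)
        e_star = abs(res.slope) * R_GAS / 1e3  # kJ/mol
        stderr_e = res.stderr * R_GAS / 1e3
        branch = "slow" if res.slope > 0 else "fast"
        return ArrheniusResult(float(e_star), float(res.intercept), branch,
                               float(stderr_e), float(res.rvalue**2), len(t))

    def plot(self, result: ArrheniusResult | None = None, ax=None):
        """ln R vs 1000/T with the fitted line (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = 1000.0 / self.series.temperatures
        ax.plot(x, np.log(self.series.rates), "o", label=self.series.site or "data")
        if result is not None and not result.flat:
            sign = +1.0 if result.branch == "slow" else -1.0
            xx = np.linspace(x.min(), x.max(), 50)
            ax.plot(xx, result.ln_a + sign * result.e_star * 1e3 / R_GAS * xx / 1000.0,
                    "-", label=f"E* = {result.e_star:.1f} kJ/mol")
        ax.set_xlabel("1000 / T (1/K)")
        ax.set_ylabel("ln R")
        ax.legend()
        return ax


def arrhenius_fit(series: RateSeries,
                  window: tuple[float, float] | None = None) -> ArrheniusResult:
    """OLS of ln(rate) on 1/T; E* = |slope| * R in kJ/mol."""
    return ArrheniusModel.from_series(series).fit(window=window)


def classify_branch(tau_c: float, nu_c_mhz: float = NU_C_DEFAULT_MHZ) -> str:
    """'slow' if tau_c is above the T1-minimum correlation time at nu_c.

    The lab-frame rate peaks near omega_C * tau ~ 0.79; motions with
    longer correlation times sit on the slow side of the maximum.
    """
    if tau_c <= 0:
        raise InvalidParameterError("tau_c must be positive")
    tau_at_max = bpp_max(SpectralDensityParams(nu_c=nu_c_mhz))[0]
    return "slow" if tau_c > tau_at_max else "fast"


# ------------------------------------------------------------ BPP model

def _omegas(params: SpectralDensityParams) -> tuple[float, float]:
    w_c = 2.0 * math.pi * params.nu_c * 1e6
    w_h = 2.0 * math.pi * params.nu_h * 1e6
    return w_c, w_h


def _j(w: float, tau: float) -> float:
    return tau / (1.0 + (w * tau) ** 2)


def bpp_rate(params: SpectralDensityParams, frame: str = "lab",
             spin_lock_nu: float | None = None) -> float:
    """Heteronuclear dipolar relaxation rate, s^-1.

    Lab frame:      R1   = C [J(wH-wC) + 3 J(wC) + 6 J(wH+wC)]
    Rotating frame: R1rho = C [1.5 J(2 w1) + J(wH-wC) + 3 J(wC) + 6 J(wH+wC)]

    with Lorentzian J(w) = tau/(1 + w^2 tau^2) and C the prefactor of
    :class:`SpectralDensityParams`. The rotating-frame form is the
    Jones-type expression whose low-frequency J(2 w1) term dominates
    when the motion matches the spin-lock nutation frequency w1.
    """
    w_c, w_h = _omegas(params)
    tau = params.tau_c
    rate = _j(w_h - w_c, tau) + 3.0 * _j(w_c, tau) + 6.0 * _j(w_h + w_c, tau)
    if frame == "rotating":
        if spin_lock_nu is None or spin_lock_nu <= 0:
            raise InvalidParameterError("rotating frame needs spin_lock_nu in kHz")
        w1 = 2.0 * math.pi * spin_lock_nu * 1e3
        rate += 1.5 * _j(2.0 * w1, tau)
    elif frame != "lab":
        raise InvalidParameterError("frame must be 'lab' or 'rotating'")
    return params.prefactor * rate


def bpp_max(params: SpectralDensityParams, frame: str = "lab",
            spin_lock_nu: float | None = None) -> tuple[float, float]:
    """(tau_at_max, max_rate) of the BPP curve at fixed frequencies."""
    from dataclasses import replace

    def neg(log_tau):
        return -bpp_rate(replace(params, tau_c=float(np.exp(log_tau))),
                         frame, spin_lock_nu)

    res = optimize.minimize_scalar(neg, bounds=(math.log(1e-14), math.log(1e-2)),
                                   method="bounded",
                                   options={"xatol": 1e-12})
    tau_max = float(np.exp(res.x))
    return tau_max, -float(res.fun)


def invert_rate_to_tau(rate: float, params: SpectralDensityParams,
                       frame: str = "lab", branch: str = "fast",
                       spin_lock_nu: float | None = None) -> float:
    """Correlation time whose BPP rate equals `rate`, on the given branch.

    The BPP curve is unimodal in tau; 'fast' selects the root below the
    maximum (short tau), 'slow' the root above. Raises NoSolutionError
    if the requested rate exceeds the maximum achievable rate.
    """
    from dataclasses import replace

    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    if branch not in ("fast", "slow"):
        raise InvalidParameterError("branch must be 'fast' or 'slow'")
    tau_max, r_max = bpp_max(params, frame, spin_lock_nu)
    if rate > r_max * (1 + 1e-12):
        raise NoSolutionError(
            f"rate {rate:.6g} s^-1 exceeds the model maximum {r_max:.6g} s^-1 "
            f"(at tau = {tau_max:.3g} s)"
        )

    def f(log_tau):
        return bpp_rate(replace(params, tau_c=float(np.exp(log_tau))),
                        frame, spin_lock_nu) - rate

    if rate >= r_max * (1 - 1e-12):
        return tau_max
    if branch == "fast":
        lo, hi = math.log(1e-16), math.log(tau_max)
    else:
        lo, hi = math.log(tau_max), math.log(1e2)
    log_tau = optimize.brentq(f, lo, hi, xtol=1e-15, rtol=8.9e-16)
    return float(np.exp(log_tau))


def r1rho_max_tau(spin_lock_nu: float) -> float:
    """Correlation time at the R1rho maximum by the matching rule.

    Operationally, the rotating-frame rate peaks when the motional
    frequency matches the spin-lock nutation frequency; the returned
    value is 1 / (spin_lock_nu in Hz), e.g. 16 us at 62.5 kHz.
    """
    if spin_lock_nu <= 0:
        raise InvalidParameterError("spin-lock frequency must be positive (kHz)")
    return 1.0 / (spin_lock_nu * 1e3)
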