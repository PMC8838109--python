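"""DSC thermodynamics of solid-solid transitions.

Integrates transition enthalpies from heat-flow or cp traces, converts
them to transition entropies dS = dH / T, measures baseline heat-capacity
steps, and evaluates entropy integrals int cp/T dT between transition
temperatures. These are the quantities that establish whether a pair of
polymorphs is enantiotropic and how much disorder each transition
unlocks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import R_GAS, SIMVASTATIN_MOLAR_MASS
from .exceptions import CoverageError, InvalidParameterError, WindowError

__all__ = [
    "DSCTrace",
    "Transition",
    "read_dsc_csv",
    "integrate_peak",
    "transition_entropy",
    "cp_step",
    "entropy_integral",
    "hindered_rotor_limit",
]


@dataclass(frozen=True)
class DSCTrace:
    """A DSC trace: temperature vs heat flow (W/g) or cp (J/(g K) or J/(mol K)).

    scan_rate in K/min; needed to convert heat flow to cp on integration.
    exo_up records the instrument's exothermic sign convention.
    """

    temperatures: np.ndarray  # K
    signal: np.ndarray
    mode: str = "heatflow"  # heatflow | cp
    scan_rate: float = 10.0
    exo_up: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.shape != y.shape:
            raise InvalidParameterError("temperatures and signal must have equal length")
        d = np.diff(t)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidParameterError("temperatures must be monotonic")
        if np.all(d < 0):  # store in ascending order
            t, y = t[::-1], y[::-1]
        if self.mode == "heatflow" and self.scan_rate == 0:
            raise InvalidParameterError("heat-flow integration needs a non-zero scan rate")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class Transition:
    """An integrated solid-solid transition."""

    t_trans: float  # K
    dh: float  # kJ/mol
    ds: float  # J/(mol K)
    order_hint: str = "lambda"  # first | second | lambda

    def __post_init__(self):
        if self.t_trans <= 0:
            raise InvalidParameterError("transition temperature must be positive")
        expected = 1e3 * self.dh / self.t_trans
        if self.ds and abs(self.ds - expected) > 1e-6 * max(abs(expected), 1.0):
            raise InvalidParameterError("dS inconsistent with dH / T")

    @classmethod
    def from_enthalpy(cls, t_trans: float, dh: float,
                      order_hint: str = "lambda") -> "Transition":
        return cls(t_trans, dh, transition_entropy(dh, t_trans), order_hint)


def read_dsc_csv(path, mode: str = "heatflow", scan_rate: float = 10.0,
                 celsius: bool | None = None, exo_up: bool = False) -> DSCTrace:
    """Read a two-column (temperature, signal) CSV.

    Temperatures in Celsius are converted to K; if `celsius` is None the
    unit is inferred (values below 150 are taken as Celsius).
    """
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    if celsius is None:
        celsius = np.max(t) < 150.0
    if celsius:
        t = t + 273.15
    return DSCTrace(t, y, mode=mode, scan_rate=scan_rate, exo_up=exo_up)


def _excess_cp(trace: DSCTrace) -> np.ndarray:
    """Trace signal converted to specific-heat units (J/(g K))."""
    if trace.mode == "cp":
        return trace.signal.copy()
    return trace.signal / (abs(trace.scan_rate) / 60.0)


def integrate_peak(trace: DSCTrace, window: tuple[float, float],
                   molar_mass: float = SIMVASTATIN_MOLAR_MASS,
                   baseline: str = "linear") -> float:
    """Transition enthalpy (kJ/mol) from a baseline-subtracted peak.

    The peak inside `window` is integrated trapezoidally over temperature
    after subtracting a baseline anchored at the window edges (linear by
    default; "sigmoid" weights the interpolation by the integrated peak
    fraction). Heat-flow traces are divided by the scan rate. A warning
    is issued when the window visibly truncates the peak.
    """
    lo, hi = min(window), max(window)
    t = trace.temperatures
    if lo < t[0] or hi > t[-1]:
        raise WindowError(f"window [{lo}, {hi}] K outside trace range "
                          f"[{t[0]:.1f}, {t[-1]:.1f}] K")
    cp = _excess_cp(trace)
    if trace.mode == "heatflow" and trace.exo_up:
        cp = -cp
    keep = (t >= lo) & (t <= hi)
    ti, yi = t[keep], cp[keep]
    if len(ti) < 5:
        raise WindowError("fewer than 5 points inside the integration window")
    if baseline == "linear":
        base = yi[0] + (yi[-1] - yi[0]) * (ti - ti[0]) / (ti[-1] - ti[0])
    elif baseline == "sigmoid":
        excess0 = yi - (yi[0] + (yi[-1] - yi[0]) * (ti - ti[0]) / (ti[-1] - ti[0]))
        cum = np.concatenate([[0.0], np.cumsum(np.diff(ti) * 0.5 *
                                               (excess0[1:] + excess0[:-1]))])
        frac = cum / cum[-1] if cum[-1] != 0 else np.zeros_like(cum)
        base = yi[0] + (yi[-1] - yi[0]) * frac
    else:
        raise InvalidParameterError("baseline must be 'linear' or 'sigmoid'")
    excess = yi - base
    area = float(np.trapezoid(excess, ti))  # J/g
    # truncation check: an edge anchored on a peak flank sits well above
    # the signal just outside the window
    peak = float(np.max(np.abs(excess)))
    for edge_t, edge_y, outside in (
        (ti[0], yi[0], (t >= lo - 2.0) & (t < lo)),
        (ti[-1], yi[-1], (t > hi) & (t <= hi + 2.0)),
    ):
        if peak > 0 and outside.sum() >= 3:
            mismatch = abs(edge_y - float(np.median(cp[outside])))
            if mismatch > 0.05 * peak:
                est_loss = mismatch * (ti[-1] - ti[0]) * 0.5
                warnings.warn(
                    f"integration window edge at {edge_t:.1f} K appears to "
                    f"truncate the peak (~{est_loss:.3g} J/g unaccounted)",
                    stacklevel=2)
    return area * molar_mass / 1e3  # kJ/mol


def transition_entropy(dh: float, t_trans: float) -> float:
    """dS = 1000 * dH / T in J/(mol K) from dH in kJ/mol and T in K."""
    if t_trans <= 0:
        raise InvalidParameterError("transition temperature must be positive")
    return 1e3 * dh / t_trans


def cp_step(trace: DSCTrace, t_star: float,
            exclude_width: float = 3.0) -> float:
    """Baseline cp step at t_star, J/(g K) (or the trace's cp unit).

    Linear baselines are fitted to the flanks below and above t_star
    (excluding +-exclude_width K around it, so a superimposed lambda
    peak does not bias them) and extrapolated to t_star; the difference
    above-minus-below is returned. Negative values mean cp drops on
    heating through t_star.
    """
    if trace.mode != "cp":
        raise InvalidParameterError("cp_step needs a cp-mode trace")
    t = trace.temperatures
    y = trace.signal
    below = t < t_star - exclude_width
    above = t > t_star + exclude_width
    if below.sum() < 5 or above.sum() < 5:
        raise WindowError("need at least 5 points on each side of t_star")
    lo_fit = np.polyfit(t[below], y[below], 1)
    hi_fit = np.polyfit(t[above], y[above], 1)
    return float(np.polyval(hi_fit, t_star) - np.polyval(lo_fit, t_star))


def entropy_integral(trace: DSCTrace, t_lo: float, t_hi: float) -> float:
    """Entropy change int_{t_lo}^{t_hi} cp / T dT for a molar-cp trace.

    The trace signal must already be molar cp in J/(mol K); the result is
    in J/(mol K) (trapezoidal quadrature).
    """
    if trace.mode != "cp":
        raise InvalidParameterError("entropy_integral needs a cp-mode trace")
    lo, hi = min(t_lo, t_hi), max(t_lo, t_hi)
    t = trace.temperatures
    if lo < t[0] or hi > t[-1]:
        raise CoverageError(f"trace does not cover [{lo}, {hi}] K")
    keep = (t >= lo) & (t <= hi)
    ti = t[keep]
    yi = trace.signal[keep]
    # include exact endpoints by interpolation
    if ti[0] > lo:
        ti = np.concatenate([[lo], ti])
        yi = np.concatenate([[np.interp(lo, t, trace.signal)], yi])
    if ti[-1] < hi:
        ti = np.concatenate([ti, [hi]])
        yi = np.concatenate([yi, [np.interp(hi, t, trace.signal)]])
    return float(np.trapezoid(yi / ti, ti))


def hindered_rotor_limit() -> float:
    """High-temperature heat-capacity limit of a free rotor, R/2 = 4.157 J/(mol K).

    Used as the documented asymptote when interpreting a cp decrease
    across an order-disorder transition: a hindered rotor's cp rises
    above this bound and converges to it from above once the barrier is
    irrelevant.
    """
    return R_GAS / 2.0
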