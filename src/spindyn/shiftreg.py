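"""NMR crystallography: GIPAW shieldings vs experimental shifts.

Computed isotropic shieldings (sigma, ppm, from plane-wave DFT MAGRES
files) are regressed against assigned experimental chemical shifts
(delta, ppm), one model per element. The residual standard deviation and
adjusted R^2 of that line are the standard agreement statistics for
validating a signal assignment against a crystal structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidParameterError

__all__ = [
    "ShieldingRecord",
    "RegressionResult",
    "ShiftRegressionModel",
    "read_magres",
    "read_shift_table",
    "fit_shift_model",
    "predict_shifts",
]


@dataclass(frozen=True)
class ShieldingRecord:
    atom_label: str
    element: str
    sigma_iso: float  # ppm


@dataclass(frozen=True)
class RegressionResult:
    """delta_exp = slope * sigma_calc + intercept, with OLS statistics.

    resid_sd uses n-2 degrees of freedom; adj_r2 is the adjusted R^2.
    """

    slope: float
    intercept: float
    resid_sd: float
    adj_r2: float
    n: int
    element: str = ""

    def summary(self) -> str:
        return "\n".join([
            f"Shielding-shift regression ({self.element or 'unspecified element'})",
            f"  n         : {self.n}",
            f"  slope     : {self.slope:.5f}",
            f"  intercept : {self.intercept:.3f} ppm",
            f"  resid sd  : {self.resid_sd:.3f} ppm",
            f"  adj R^2   : {self.adj_r2:.5f}",
        ])


def read_magres(path) -> list[ShieldingRecord]:
    """Parse the ms (magnetic shielding) block of a MAGRES file.

    Returns one record per atom with sigma_iso = trace/3 of the 3x3
    shielding tensor. Lines look like
    ``ms C 1 s11 s12 s13 s21 s22 s23 s31 s32 s33``.
    """
    records: list[ShieldingRecord] = []
    in_magres = False
    saw_block = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("[magres]"):
                in_magres, saw_block = True, True
                continue
            if line.startswith("[/magres]"):
                in_magres = False
                continue
            if not in_magres or not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] != "ms":
                continue
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: malformed ms line "
                    f"(expected 'ms elem index' + 9 tensor components, got "
                    f"{len(parts)} fields)")
            try:
                tensor = [float(x) for x in parts[3:12]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric tensor "
                                  f"component ({exc})") from None
            element = parts[1]
            label = f"{element}{parts[2]}"
            sigma_iso = (tensor[0] + tensor[4] + tensor[8]) / 3.0
            records.append(ShieldingRecord(label, element, sigma_iso))
    if not saw_block:
        raise FormatError(f"{path}: no [magres] block found")
    if not records:
        import warnings

        warnings.warn(f"{path}: empty ms block", stacklevel=2)
    return records


def read_shift_table(path) -> pd.DataFrame:
    """Experimental shifts as CSV with columns label, element, delta_ppm."""
    df = pd.read_csv(path)
    missing = {"label", "element", "delta_ppm"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


class ShiftRegressionModel:
    """OLS of experimental shifts on computed shieldings for one element.

    ``fixed_slope`` switches to a referencing mode where the slope is
    constrained (commonly -1) and only the intercept is estimated.
    """

    def __init__(self, sigma_calc, delta_exp, element: str = "",
                 fixed_slope: float | None = None):
        sigma = np.asarray(sigma_calc, dtype=float)
        delta = np.asarray(delta_exp, dtype=float)
        if sigma.shape != delta.shape or sigma.ndim != 1:
            raise InvalidParameterError("sigma and delta must be 1-D, equal length")
        if len(sigma) < 3:
            raise InvalidParameterError("need at least 3 (sigma, delta) pairs")
        self.sigma = sigma
        self.delta = delta
        self.element = element
        self.fixed_slope = fixed_slope

    @classmethod
    def from_records(cls, records, shifts: pd.DataFrame, element: str,
                     fixed_slope: float | None = None) -> "ShiftRegressionModel":
        """Pair MAGRES records with a shift table on atom label."""
        calc = {r.atom_label: r.sigma_iso for r in records if r.element == element}
        sub = shifts[shifts["element"] == element]
        pairs = [(calc[lbl], d) for lbl, d in zip(sub["label"], sub["delta_ppm"])
                 if lbl in calc]
        if len(pairs) < 3:
            raise InvalidParameterError(
                f"fewer than 3 matched {element} label pairs")
        sig, del_ = zip(*pairs)
        return cls(sig, del_, element=element, fixed_slope=fixed_slope)

    def fit(self) -> RegressionResult:
        x, y = self.sigma, self.delta
        n = len(x)
        if np.ptp(x) == 0:
            raise InvalidParameterError("computed shieldings are constant (rank deficient)")
        if self.fixed_slope is None:
            slope, intercept = np.polyfit(x, y, 1)
        else:
            slope = float(self.fixed_slope)
            intercept = float(np.mean(y - slope * x))
        resid = y - (slope * x + intercept)
        ssr = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        resid_sd = np.sqrt(ssr / (n - 2))
        r2 = 1.0 - ssr / sst if sst > 0 else 0.0
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        return RegressionResult(float(slope), float(intercept), float(resid_sd),
                                float(adj_r2), n, self.element)


def fit_shift_model(sigma_calc, delta_exp, element: str = "",
                    fixed_slope: float | None = None) -> RegressionResult:
    """Convenience wrapper: fit delta_exp on sigma_calc by OLS."""
    return ShiftRegressionModel(sigma_calc, delta_exp, element,
                                fixed_slope=fixed_slope).fit()


def predict_shifts(records, model: RegressionResult) -> pd.DataFrame:
    """delta_pred = slope * sigma + intercept for each matching record.

    Returns a residual-friendly table (label, element, sigma_iso,
    delta_pred) for outlier inspection; records of other elements are
    excluded.
    """
    if model.element:
        records = [r for r in records if r.element == model.element]
    if not records:
        raise InvalidParameterError(
            f"no shielding records for element {model.element!r}")
    rows = [(r.atom_label, r.element, r.sigma_iso,
             model.slope * r.sigma_iso + model.intercept) for r in records]
    return pd.DataFrame(rows, columns=["label", "element", "sigma_iso", "delta_pred"])
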