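"""End-to-end orchestration: per-site motional-regime classification.

A YAML (or dict) config describes, per molecular site, where its
evidence comes from — dipolar powder slices (order parameter S),
variable-temperature rate series (activation energy E* and branch),
correlation times — either as file paths or as synthetic-generation
blocks. The stages run in the order thermo -> relax -> dipolar ->
motion, results are joined per site, and each site is labelled

* ``fast``          S <= s2_fast and fast-branch thermal activation,
* ``rigid``         S >= s2_rigid and a flat (or absent) E* window,
* ``intermediate``  everything else,

with thresholds taken from the config (defaults 0.5 / 0.95, chosen
inside the gap between the observed fast band ~0.33-0.38 and the
restricted band ~0.91-1.00). The labels are descriptive, not claims of
crystallographic phase boundaries: DSC transition temperatures are
inputs, never outputs, of this step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SpinDynError
from . import dipolar, motion, relax, synthgen, thermo

__all__ = ["RegimeReport", "StageError", "run", "classify_regime",
           "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS = {"s2_fast": 0.5, "s2_rigid": 0.95, "e_flat": 2.0}


class StageError(SpinDynError):
    """A stage's input is missing or unreadable; names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class RegimeReport:
    site: str
    temperature_range: tuple[float, float] | None
    regime: str  # rigid | intermediate | fast
    evidence: tuple[tuple[str, float | str], ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "temperature_range": list(self.temperature_range)
            if self.temperature_range else None,
            "regime": self.regime,
            "evidence": {k: v for k, v in self.evidence},
        }


def classify_regime(s2: float | None, e_star: float | None, branch: str | None,
                    thresholds: dict | None = None) -> str:
    """Label a site from its order parameter and Arrhenius evidence."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    if s2 is not None and s2 <= th["s2_fast"] and branch == "fast":
        return "fast"
    if s2 is not None and s2 >= th["s2_rigid"] and (
        e_star is None or e_star <= th["e_flat"]
    ):
        return "rigid"
    return "intermediate"


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    import yaml

    with open(config) as fh:
        return yaml.safe_load(fh)


def _site_seed(base_seed: int, site_name: str, stage: str) -> int:
    """Stable per-site, per-stage sub-seed below 2**31."""
    h = hashlib.sha256(f"{base_seed}:{site_name}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _dipolar_stage(site_cfg: dict, name: str, seed: int, log: list) -> dict:
    cfg = site_cfg.get("dipolar")
    if cfg is None:
        return {}
    if "s2" in cfg:
        return {"S2": float(cfg["s2"])}
    if "pattern_csv" in cfg:
        try:
            df = pd.read_csv(cfg["pattern_csv"])
        except OSError as exc:
            raise StageError("dipolar", f"site {name}: {exc}") from exc
        pattern = dipolar.DipolarPattern(
            df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float),
            site=name, scale_applied=float(cfg.get("scale_applied", 1.0)))
        log.append(("dipolar", name, _hash_array(pattern.intensities)))
    elif "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        syn.setdefault("seed", seed)
        pattern = synthgen.gen_pake(site=name, **syn)
        log.append(("dipolar", name, _hash_array(pattern.intensities)))
    else:
        raise StageError("dipolar", f"site {name}: need s2, pattern_csv or synthetic")
    d_eff, unc = dipolar.extract_splitting(pattern)
    d_rig = float(cfg.get("d_rig", dipolar.rigid_limit_D()))
    res = dipolar.coupling_result(d_eff, d_rig, pattern.scale_applied, unc)
    return {"S2": res.s2, "D_eff_kHz": res.d_eff, "D_rig_kHz": res.d_rig}


def _relax_stage(site_cfg: dict, name: str, seed: int, log: list) -> dict:
    cfg = site_cfg.get("relax")
    if cfg is None:
        return {}
    if "series_csv" in cfg:
        try:
            df = pd.read_csv(cfg["series_csv"])
        except OSError as exc:
            raise StageError("relax", f"site {name}: {exc}") from exc
        series = relax.RateSeries(df["T_K"].to_numpy(float),
                                  df["rate_s-1"].to_numpy(float), site=name)
    elif "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        truth = synthgen.GroundTruth(
            e_star=syn["e_star"], a=syn.get("a", 1.0),
            noise_sd=syn.get("noise_sd", 0.0), seed=syn.get("seed", seed))
        series = synthgen.gen_rate_series(
            truth, syn["temperatures"], branch=syn.get("branch", "fast"), site=name)
    else:
        raise StageError("relax", f"site {name}: need series_csv or synthetic")
    log.append(("relax", name, _hash_array(series.rates)))
    window = cfg.get("window")
    result = relax.arrhenius_fit(series, window=tuple(window) if window else None)
    out = {"E_star_kJ_mol": result.e_star, "branch": result.branch,
           "r_squared": result.r_squared}
    if result.flat:
        out["branch"] = "flat"
    return out


def _motion_stage(site_cfg: dict, evidence: dict) -> dict:
    out = {}
    tau = site_cfg.get("tau_c")
    if tau is not None:
        out["tau_c_s"] = float(tau)
        out["dipolar_averaging"] = motion.classify_averaging(float(tau))
    s2 = evidence.get("S2")
    if s2 is not None and s2 > 0.8:  # wobble inversion only in its validity range
        out["theta_rms_deg"] = motion.wobble_angle(min(s2, 1.0))
    return out


def _hash_array(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def run(config) -> dict:
    """Execute the pipeline; returns reports, thermo artifacts and a log.

    Returns a dict with keys ``reports`` (list of RegimeReport),
    ``transitions`` (list of thermo.Transition from the optional DSC
    stage), ``log`` (per-stage input hashes) and ``json`` (the
    deterministic serialised report).
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    thresholds = {**DEFAULT_THRESHOLDS, **cfg.get("thresholds", {})}
    log: list = []
    transitions: list[thermo.Transition] = []

    dsc_cfg = cfg.get("dsc")
    if dsc_cfg is not None:
        if "trace_csv" in dsc_cfg:
            try:
                trace = thermo.read_dsc_csv(dsc_cfg["trace_csv"],
                                            mode=dsc_cfg.get("mode", "heatflow"),
                                            scan_rate=dsc_cfg.get("scan_rate", 10.0))
            except OSError as exc:
                raise StageError("thermo", str(exc)) from exc
        elif "synthetic" in dsc_cfg:
            syn = dict(dsc_cfg["synthetic"])
            syn.setdefault("seed", _site_seed(seed, "__dsc__", "thermo"))
            trace = synthgen.gen_dsc(**syn)
        else:
            raise StageError("thermo", "need trace_csv or synthetic")
        log.append(("thermo", "dsc", _hash_array(trace.signal)))
        for window in dsc_cfg.get("windows", []):
            dh = thermo.integrate_peak(trace, tuple(window),
                                       molar_mass=dsc_cfg.get(
                                           "molar_mass",
                                           thermo.SIMVASTATIN_MOLAR_MASS))
            t_peak = float(trace.temperatures[
                (trace.temperatures >= min(window))
                & (trace.temperatures <= max(window))][np.argmax(
                    trace.signal[(trace.temperatures >= min(window))
                                 & (trace.temperatures <= max(window))])])
            transitions.append(thermo.Transition.from_enthalpy(t_peak, dh))

    reports: list[RegimeReport] = []
    for site_cfg in cfg.get("sites", []):
        name = site_cfg["name"]
        evidence: dict = {}
        evidence.update(_dipolar_stage(site_cfg, name,
                                       _site_seed(seed, name, "dipolar"), log))
        evidence.update(_relax_stage(site_cfg, name,
                                     _site_seed(seed, name, "relax"), log))
        evidence.update(_motion_stage(site_cfg, evidence))
        regime = classify_regime(evidence.get("S2"),
                                 evidence.get("E_star_kJ_mol"),
                                 evidence.get("branch"), thresholds)
        t_range = site_cfg.get("temperature_range")
        reports.append(RegimeReport(
            site=name,
            temperature_range=tuple(t_range) if t_range else None,
            regime=regime,
            evidence=tuple(sorted(evidence.items())),
        ))

    payload = {
        "thresholds": thresholds,
        "transitions": [
            {"T_K": tr.t_trans, "dH_kJ_mol": round(tr.dh, 10),
             "dS_J_mol_K": round(tr.ds, 10)} for tr in transitions
        ],
        "reports": [r.to_dict() for r in reports],
    }
    report_json = json.dumps(payload, sort_keys=True, indent=1)
    return {"reports": reports, "transitions": transitions, "log": log,
            "json": report_json}


def markdown_summary(result: dict) -> str:
    """One-row-per-site Markdown table of the regime report."""
    lines = ["| site | T range (K) | regime | evidence |",
             "|---|---|---|---|"]
    for r in result["reports"]:
        tr = (f"{r.temperature_range[0]:g}-{r.temperature_range[1]:g}"
              if r.temperature_range else "-")
        ev = ", ".join(
            f"{k}={v:.3g}" if isinstance(v, float) else f"{k}={v}"
            for k, v in r.evidence)
        lines.append(f"| {r.site} | {tr} | {r.regime} | {ev} |")
    return "\n".join(lines)
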