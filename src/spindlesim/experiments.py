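"""Calibration and the reconfiguration experiments.

Three campaigns, all config-driven and deterministic:

* morphology sweeps — terminal / preterminal length multipliers against the
  calibrated base, reporting the three encoding features and percent changes
  (reductions positive);
* 2-D terminal conductance sweeps — Nav1.6 density (pS/um^2) against KCNQ
  density (S/cm^2) in the receptor terminals, with a static-failure mask;
* phase-transition localization — at fixed KCNQ, the narrow Nav1.6 span over
  which static firing goes from absent to its local plateau rate.

``fit_base_model`` is the calibration entry point: a bounded derivative-free
search over the transduction weights (and optionally fibre gains) that
minimizes relative error to a prototypical response. The shipped defaults
are the frozen result of this calibration; rerunning it is only needed after
changing model structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from spindlesim import config as cfgmod
from spindlesim import pipeline as pl
from spindlesim.features import FiringFeatures, percent_change

__all__ = [
    "SweepSpec",
    "SweepResult",
    "fit_base_model",
    "sweep_morphology",
    "sweep_conductance_2d",
    "find_phase_transition",
    "channel_knockout",
    "hold_isi_cv",
]

#: hold-phase ISI coefficient of variation above which a run is flagged
#: irregular (bi-stable / stochastic-looking firing)
IRREGULAR_CV = 0.3


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: which config entry varies and over which grid."""

    parameter: str                      # "terminal" | "preterminal" | "nav16" | "kcnq"
    values: tuple = ()
    base_config: dict | None = None

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("sweep grid must be non-empty")
        if not all(np.isfinite(self.values)):
            raise ValueError("sweep grid must be finite")


@dataclass
class SweepResult:
    """Tidy per-point results of a sweep (base point included)."""

    parameter: str
    points: list[dict] = field(default_factory=list)
    base: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.points:
            for feat in ("initial_burst_pps", "peak_dynamic_pps", "static_avg_pps"):
                rows.append({
                    "parameter": self.parameter,
                    "value": p["value"],
                    "feature": feat,
                    "rate_pps": p["features"][feat],
                    "pct_change": p["pct_change"][feat],
                    "flags": ";".join(p["features"]["flags"]),
                    "config_hash": p["config_hash"],
                })
        return pd.DataFrame(rows)


def hold_isi_cv(result: pl.PipelineResult) -> float:
    """Coefficient of variation of the hold-phase ISIs (irregularity metric)."""
    ph = result.ramp_spec.phase_times()
    t = result.spikes.times
    m = (t >= ph["ramp_off"]) & (t <= ph["release_on"])
    isi = np.diff(t[m])
    if isi.size < 3:
        return float("nan")
    return float(np.std(isi) / np.mean(isi))


def _evaluate(cfg: dict, overrides: dict | None = None) -> pl.PipelineResult:
    return pl.run_pipeline(cfg, overrides)


def _pct_changes(f: FiringFeatures, base: FiringFeatures) -> dict:
    out = {}
    for key in ("initial_burst_pps", "peak_dynamic_pps", "static_avg_pps"):
        b = getattr(base, key)
        out[key] = percent_change(getattr(f, key), b) if b > 0 else float("nan")
    return out


def _point(value, cfg, overrides, base_feat) -> dict:
    res = _evaluate(cfg, overrides)
    f = res.features
    merged = cfgmod.merge_config(cfg, overrides or {})
    return {
        "value": value,
        "features": f.as_dict(),
        "pct_change": _pct_changes(f, base_feat),
        "irregular": bool(hold_isi_cv(res) > IRREGULAR_CV),
        "config_hash": cfgmod.config_hash(merged),
    }


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

DEFAULT_PROTOTYPE = {
    "initial_burst_pps": 150.0,
    "peak_dynamic_pps": 100.0,
    "static_avg_pps": 65.0,
}

FREE_PARAM_PATHS = {
    "kfb": ("transduction", "kfb"),
    "kyb": ("transduction", "kyb"),
    "kfc": ("transduction", "kfc"),
    "scale": ("transduction", "scale"),
}


def _get(cfg, path):
    d = cfg
    for k in path[:-1]:
        d = d[k]
    return d[path[-1]]


def _set(cfg, path, value):
    d = cfg
    for k in path[:-1]:
        d = d[k]
    d[path[-1]] = value


def fit_base_model(
    prototype: dict | None = None,
    free_params: Sequence[str] = ("kfb", "kfc"),
    cfg: dict | None = None,
    rel_tol: float = 0.15,
    max_iter: int = 40,
    evaluate: Callable[[dict], FiringFeatures] | None = None,
) -> tuple[dict, dict]:
    """Calibrate free transduction parameters to a prototypical response.

    Bounded derivative-free search (log-space Nelder-Mead) minimizing the
    mean relative feature error; a configuration whose error is already
    within ``rel_tol`` is returned unchanged. The fit additionally requires
    the prototypical ordering (initial burst > 100 pps, peak dynamic >
    static average > 0); the best point is reported even when the tolerance
    is not reached (``report["converged"]`` is False then).

    Returns ``(calibrated_config, report)``.
    """
    from scipy.optimize import minimize

    if prototype is None:
        prototype = DEFAULT_PROTOTYPE
    if cfg is None:
        cfg = cfgmod.default_config()
    for name in free_params:
        if name not in FREE_PARAM_PATHS:
            raise KeyError(f"unknown free parameter {name!r}")
    if evaluate is None:
        evaluate = lambda c: pl.run_pipeline(c).features  # noqa: E731

    def error(feats: FiringFeatures) -> float:
        errs = [
            abs(getattr(feats, k) - v) / v
            for k, v in prototype.items()
        ]
        penalty = 0.0
        if feats.initial_burst_pps <= 100.0:
            penalty += 1.0
        if not (feats.peak_dynamic_pps > feats.static_avg_pps > 0.0):
            penalty += 1.0
        return float(np.mean(errs) + penalty)

    start_feats = evaluate(cfg)
    best = (error(start_feats), cfg, start_feats)
    if best[0] <= rel_tol:
        return cfg, {
            "converged": True, "iterations": 0, "error": best[0],
            "features": start_feats.as_dict(),
        }

    paths = [FREE_PARAM_PATHS[n] for n in free_params]
    x0 = np.log([_get(cfg, p) for p in paths])
    n_eval = 0

    def objective(x):
        nonlocal best, n_eval
        n_eval += 1
        trial = cfgmod.merge_config(cfg, {})
        for p, xv in zip(paths, x):
            _set(trial, p, float(np.exp(np.clip(xv, x0.min() - 3, x0.max() + 3))))
        feats = evaluate(trial)
        e = error(feats)
        if e < best[0]:
            best = (e, trial, feats)
        return e

    minimize(objective, x0, method="Nelder-Mead",
             options={"maxfev": max_iter, "xatol": 0.02, "fatol": rel_tol / 4})
    e, calibrated, feats = best
    return calibrated, {
        "converged": bool(e <= rel_tol), "iterations": n_eval, "error": e,
        "features": feats.as_dict(),
    }


# --------------------------------------------------------------------------
# sweeps
# --------------------------------------------------------------------------

_MORPH_KEYS = {
    "terminal": "terminal_length_multiplier",
    "preterminal": "preterminal_length_multiplier",
}


def sweep_morphology(spec: SweepSpec) -> SweepResult:
    """Length-multiplier sweep of the terminal or preterminal region.

    One simulation per multiplier; individual failures are recorded and the
    sweep continues. The base point (multiplier 1) is always included.
    """
    if spec.parameter not in _MORPH_KEYS:
        raise ValueError("morphology sweeps accept 'terminal' or 'preterminal'")
    cfg = spec.base_config or cfgmod.default_config()
    key = _MORPH_KEYS[spec.parameter]
    base_res = _evaluate(cfg)
    base_feat = base_res.features
    result = SweepResult(parameter=spec.parameter)
    result.base = _point(1.0, cfg, None, base_feat)
    values = sorted(set(spec.values) | {1.0})
    for m in values:
        try:
            result.points.append(
                _point(m, cfg, {"morphology": {key: float(m)}}, base_feat)
            )
        except Exception as exc:  # individual run failure
            result.points.append({
                "value": m, "error": repr(exc), "features": None,
                "pct_change": None, "config_hash": "",
            })
    return result


def sweep_conductance_2d(
    nav16_ps_um2: Sequence[float],
    kcnq_s_cm2: Sequence[float],
    base_config: dict | None = None,
) -> SweepResult:
    """2-D sweep of terminal Nav1.6 (pS/um^2) x terminal KCNQ (S/cm^2).

    Returns one point per grid cell with the static-failure flag; the
    calibrated base cell is the reference for percent changes.
    """
    cfg = base_config or cfgmod.default_config()
    base_feat = _evaluate(cfg).features
    result = SweepResult(parameter="nav16_x_kcnq")
    result.base = _point((cfg["densities"]["terminal"]["nav16"],
                          cfg["densities"]["terminal"]["kcnq"]), cfg, None, base_feat)
    for kv in kcnq_s_cm2:
        for na in nav16_ps_um2:
            ov = {"densities": {"terminal": {"nav16": float(na), "kcnq": float(kv)}}}
            try:
                p = _point((float(na), float(kv)), cfg, ov, base_feat)
                p["nav16"] = float(na)
                p["kcnq"] = float(kv)
                p["static_failed"] = p["features"]["static_avg_pps"] == 0.0
                result.points.append(p)
            except Exception as exc:
                result.points.append({
                    "value": (na, kv), "nav16": float(na), "kcnq": float(kv),
                    "error": repr(exc), "features": None, "pct_change": None,
                    "static_failed": True, "config_hash": "",
                })
    return result


def _static_rate(cfg: dict, nav16: float, kcnq: float) -> float:
    ov = {"densities": {"terminal": {"nav16": float(nav16), "kcnq": float(kcnq)}}}
    return _evaluate(cfg, ov).features.static_avg_pps


def find_phase_transition(
    kcnq_s_cm2: float,
    nav16_lo: float = 0.0,
    nav16_hi: float = 50.0,
    base_config: dict | None = None,
    tol_ps_um2: float = 0.1,
    n_profile: int = 25,
) -> dict:
    """Locate the static-firing phase transition along Nav1.6 at fixed KCNQ.

    Bisects the Nav1.6 density between the last failing and first competent
    point to ``tol_ps_um2``, then profiles the static rate above onset and
    reports the transition width: the Nav1.6 span between 10% and 90% of the
    local plateau rate (the rate at ``nav16_hi``).

    Returns a dict with ``found``, ``onset``, ``width_ps_um2`` and the
    profiled points.
    """
    cfg = base_config or cfgmod.default_config()
    lo, hi = float(nav16_lo), float(nav16_hi)
    r_lo = _static_rate(cfg, lo, kcnq_s_cm2)
    r_hi = _static_rate(cfg, hi, kcnq_s_cm2)
    if r_lo > 0.0 and r_hi > 0.0:
        return {"found": False, "reason": "static firing competent across range"}
    if r_hi == 0.0:
        return {"found": False, "reason": "static firing fails across range"}
    while hi - lo > tol_ps_um2:
        mid = 0.5 * (lo + hi)
        if _static_rate(cfg, mid, kcnq_s_cm2) > 0.0:
            hi = mid
        else:
            lo = mid
    onset = hi
    plateau = r_hi
    xs = np.linspace(onset, nav16_hi, n_profile)
    rates = np.array([_static_rate(cfg, x, kcnq_s_cm2) for x in xs])

    def first_crossing(level: float) -> float:
        above = rates >= level
        if not above.any():
            return float(nav16_hi)
        i = int(np.argmax(above))
        if i == 0 or rates[i] == rates[i - 1]:
            return float(xs[i])
        w = (level - rates[i - 1]) / (rates[i] - rates[i - 1])
        return float(xs[i - 1] + w * (xs[i] - xs[i - 1]))

    x10 = first_crossing(0.1 * plateau)
    x90 = first_crossing(0.9 * plateau)
    return {
        "found": True,
        "kcnq": float(kcnq_s_cm2),
        "onset": float(onset),
        "width_ps_um2": max(x90 - x10, tol_ps_um2),
        "profile": [{"nav16": float(x), "static_avg_pps": float(r)}
                    for x, r in zip(xs, rates)],
        "plateau_pps": float(plateau),
    }


def channel_knockout(cfg: dict, channel_name: str) -> dict:
    """Zero the named channel's density in every region (all else untouched)."""
    densities = cfg.get("densities", {})
    present = any(channel_name in row for row in densities.values())
    if not present:
        from spindlesim.channels import CHANNEL_NAMES
        if channel_name not in CHANNEL_NAMES:
            raise KeyError(f"unknown channel {channel_name!r}")
    out = cfgmod.merge_config(cfg, {})
    for region, row in out.get("densities", {}).items():
        if channel_name in row:
            row[channel_name] = 0.0
    return out
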