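"""End-to-end pipeline: curves -> calibrations -> flow -> EI maps -> report.

The run configuration is a plain (YAML-loadable) mapping; `run_pipeline`
executes the requested stages and returns a JSON-serializable report holding
calibration coefficients and R^2, Lineweaver-Burke parameters per
condition/phase, flow and wall-shear-stress summaries, wall/center EI ratios,
and the seeds needed to reproduce the run.  Reports contain no timestamps, so
identical configuration and seed give byte-identical reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import PRESETS, fit_calibration, preset_for_condition
from .ektacytometry import CANONICAL_SS, DeformabilityCurve, lineweaver_burke_fit
from .ei_map import compare_conditions, map_ei, wall_center_ratios
from .errors import ConfigurationError
from .flow import (
    Channel,
    FlowProblem,
    PulseProfile,
    Tube,
    solve_pulsatile,
    solve_steady,
    wall_shear_stress,
)
from .io import export_fields, read_curves, write_curves
from .rheology import CassonParams
from .synth import SynthConfig, generate_dataset

DEFAULT_STAGES = ("curves", "lb", "calibration", "flow", "ei_map")


def parse_rheology(cfg: dict | None) -> CassonParams:
    cfg = dict(cfg or {})
    return CassonParams(
        hct=cfg.get("hct", 0.4),
        mu0=cfg.get("mu0_pa_s", 1.45e-3),
        mu_fallback=cfg.get("mu_fallback_pa_s", 0.0035),
        mu_cap=cfg.get("mu_cap_pa_s", 2.072e-2),
        preset=cfg.get("preset", "literal"),
    )


def parse_flow_problem(cfg: dict | None) -> FlowProblem:
    cfg = dict(cfg or {})
    g = dict(cfg.get("geometry") or {})
    kind = g.get("kind", "channel")
    if kind == "channel":
        geometry = Channel(
            half_height=g.get("half_height", 0.00315), length=g.get("length", 0.06)
        )
    elif kind == "tube":
        geometry = Tube(radius=g.get("radius", 0.00315), length=g.get("length", 0.06))
    else:
        raise ConfigurationError(f"unknown geometry kind {kind!r}")
    i = dict(cfg.get("inlet") or {})
    if i.get("kind", "pulse") == "pulse":
        inlet = PulseProfile(
            v_min=i.get("v_min", 0.1),
            v_max=i.get("v_max", 0.5),
            period=i.get("period", 0.5),
        )
    else:
        inlet = float(i.get("velocity", 0.3))
    grid = dict(cfg.get("grid") or {})
    return FlowProblem(
        geometry=geometry,
        inlet=inlet,
        outlet_gauge_pressure=cfg.get("outlet_gauge_pressure_pa", 13332.0),
        rho=cfg.get("rho_kg_m3", 1060.0),
        rheology=parse_rheology(cfg.get("rheology")),
        nx=grid.get("nx", 256),
        ny=grid.get("ny", 64),
        dt=cfg.get("dt_s"),
        n_periods=cfg.get("n_periods", 2),
        n_store=cfg.get("n_store", 20),
    )


def mean_curve(curves, condition: str, phase: str | None = None) -> DeformabilityCurve:
    """Pointwise mean curve over all curves of one condition (and phase)."""
    sel = [
        c
        for c in curves
        if c.condition == condition and (phase is None or c.phase == phase)
    ]
    if not sel:
        raise ConfigurationError(f"no curves for condition={condition}, phase={phase}")
    grid = sel[0].ss
    ei = np.mean([c.ei for c in sel], axis=0)
    return DeformabilityCurve(
        ss=grid.copy(), ei=ei, condition=condition,
        phase=phase or sel[0].phase, subject_id="mean", replicate=1,
    )


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages and return the run report."""
    seed = int(config.get("seed", 0))
    stages = tuple(config.get("stages", DEFAULT_STAGES))
    report: dict = {
        "package": "rbc_oxyshear",
        "version": __version__,
        "seed": seed,
        "stages": list(stages),
    }

    # --- curves: synthetic generation or CSV ingestion -----------------------
    if "curves" not in stages:
        return report
    if config.get("curves_csv"):
        curves = read_curves(config["curves_csv"])
        report["curves"] = {"source": str(config["curves_csv"]), "n_curves": len(curves)}
    else:
        scfg = dict(config.get("synth") or {})
        scfg.setdefault("seed", seed)
        synth_cfg = SynthConfig(**scfg)
        curves = generate_dataset(synth_cfg)
        report["curves"] = {
            "source": "synthetic",
            "n_curves": len(curves),
            "synth_seed": synth_cfg.seed,
            "noise_sd": synth_cfg.noise_sd,
            "subject_sd": synth_cfg.subject_sd,
        }
        if config.get("curves_out"):
            write_curves(curves, config["curves_out"])

    conditions = sorted({c.condition for c in curves})
    phases = sorted({c.phase for c in curves})

    # --- Lineweaver-Burke parameterization ----------------------------------
    if "lb" in stages:
        lb_report = {}
        for condition in conditions:
            for phase in phases:
                mc = mean_curve(curves, condition, phase)
                lb = lineweaver_burke_fit(mc)
                lb_report[f"{condition}/{phase}"] = {
                    "ei_max": lb.ei_max,
                    "ss_half_pa": lb.ss_half,
                    "ratio_pa": lb.ratio,
                    "r2_linear": lb.r2_linear,
                    "n_used": lb.n_used,
                    "n_excluded": lb.n_excluded,
                }
        report["lineweaver_burke"] = lb_report

    # --- calibrations --------------------------------------------------------
    cals = {}
    if "calibration" in stages:
        cal_cfg = dict(config.get("calibration") or {})
        cal_report = {}
        for condition in conditions:
            if cal_cfg.get("use_presets", False):
                cal = preset_for_condition(condition)
            else:
                mc = mean_curve(curves, condition, phase="before_5Pa")
                cal = fit_calibration(
                    mc, n_starts=cal_cfg.get("n_starts", 8), seed=seed
                )
            cals[condition] = cal
            cal_report[condition] = {
                "c1": cal.c1, "r1_per_pa": cal.r1,
                "c2": cal.c2, "r2_per_pa": cal.r2,
                "r_squared": cal.r_squared,
                "fit_domain_pa": list(cal.fit_domain),
                "preset": cal.name,
            }
        report["calibrations"] = cal_report
    else:
        cals = {c.condition: c for c in PRESETS.values()}

    # --- flow ----------------------------------------------------------------
    if "flow" not in stages:
        return report
    problem = parse_flow_problem(config.get("flow"))
    if isinstance(problem.inlet, PulseProfile):
        result = solve_pulsatile(problem)
        fields = result.fields
        report["flow"] = {
            "kind": "pulsatile",
            "n_phases": len(fields),
            "period_s": problem.inlet.period,
            "period_change_m_s": result.period_change,
            "mean_inlet_velocity_m_s": result.mean_inlet_velocity,
            "sweeps": result.sweeps,
        }
    else:
        fields = [solve_steady(problem)]
        report["flow"] = {"kind": "steady", "inlet_velocity_m_s": float(problem.inlet)}
    wss = [wall_shear_stress(f) for f in fields]
    report["flow"].update(
        {
            "wss_pa_per_phase": [float(w.wss[0]) for w in wss],
            "wss_pa_mean": float(np.mean([w.wss[0] for w in wss])),
            "pressure_gradient_pa_m_per_phase": [f.pressure_gradient for f in fields],
            "v_mean_m_s_per_phase": [f.v_mean for f in fields],
        }
    )

    # --- EI maps -------------------------------------------------------------
    if "ei_map" in stages:
        ei_report = {}
        ei_by_phase = {}
        for condition in conditions:
            cal = cals[condition]
            ei_fields = [map_ei(f, cal) for f in fields]
            for k, e in enumerate(ei_fields):
                ei_by_phase.setdefault(k, []).append(e)
            ratios = wall_center_ratios(ei_fields)
            ei_report[condition] = {
                "calibration_id": ei_fields[0].calibration_id,
                "ei_min": float(min(e.ei[e.mask].min() for e in ei_fields)),
                "ei_max": float(max(e.ei[e.mask].max() for e in ei_fields)),
                "wall_center_ratio_per_phase": ratios["ratios"],
                "wall_center_ratio_min": ratios["min_ratio"],
                "wall_center_ratio_max": ratios["max_ratio"],
            }
        if set(conditions) >= {"oxygenated", "deoxygenated"}:
            per_phase = [
                compare_conditions(
                    next(e for e in ei_by_phase[k] if e.condition == "oxygenated"),
                    next(e for e in ei_by_phase[k] if e.condition == "deoxygenated"),
                )
                for k in sorted(ei_by_phase)
            ]
            ei_report["comparison"] = {
                "fraction_deoxy_higher_min": min(
                    c["fraction_deoxy_higher"] for c in per_phase
                ),
                "min_difference": float(min(c["difference"].min() for c in per_phase)),
                "max_difference": float(max(c["difference"].max() for c in per_phase)),
            }
        report["ei"] = ei_report
        if config.get("output", {}).get("fields_dir"):
            export_fields(
                fields, config["output"]["fields_dir"], ei_fields_by_phase=ei_by_phase
            )

    out = config.get("output", {}).get("report")
    if out:
        Path(out).parent.mkdir(parents=True, exist_ok=True)
        with open(out, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
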