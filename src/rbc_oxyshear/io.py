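"""File I/O: the curves CSV dialect, VTK legacy field export, YAML config.

CSV dialect: header ``shear_stress_pa,ei,condition,phase,subject,replicate``,
decimal point, comma separator, UTF-8.  Units are carried in column names
(stresses in Pa) to avoid silent mPa*s/Pa confusion.  Extra columns are
tolerated and ignored with a log line.

Field export writes VTK legacy ASCII structured-grid files (one per stored
phase) readable by ParaView/VisIt, with point-data arrays ``u,v,p,gamma_dot,
mu,tau`` plus any EI arrays.  Output is byte-deterministic for identical
inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ektacytometry import DeformabilityCurve
from .errors import GridMismatchError, SchemaError

log = logging.getLogger("rbc_oxyshear")

REQUIRED_COLUMNS = ["shear_stress_pa", "ei", "condition", "phase", "subject", "replicate"]


def write_curves(curves, path) -> None:
    """Write curves in the standard CSV dialect (row order = curve order)."""
    rows = []
    for c in curves:
        for s, e in zip(c.ss, c.ei):
            rows.append(
                {
                    "shear_stress_pa": s,
                    "ei": e,
                    "condition": c.condition,
                    "phase": c.phase,
                    "subject": c.subject_id,
                    "replicate": c.replicate,
                }
            )
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)


def read_curves(path) -> list[DeformabilityCurve]:
    """Read curves from the standard CSV dialect, preserving row order.

    Rows are grouped into curves by (condition, phase, subject, replicate) in
    order of first appearance; shear stresses within a curve must be strictly
    increasing.  Missing columns raise SchemaError naming the column;
    non-numeric EI/SS raise SchemaError naming the first offending line.
    """
    df = pd.read_csv(path, dtype={"subject": str}, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        log.info("ignoring extra columns %s in %s", extra, path)

    for col in ("shear_stress_pa", "ei"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(
                f"non-numeric or missing {col!r} at line {line} of {path}"
            )
        df[col] = vals

    curves = []
    seen = {}
    for key, group in df.groupby(
        ["condition", "phase", "subject", "replicate"], sort=False
    ):
        condition, phase, subject, replicate = key
        if key in seen:
            raise SchemaError(f"curve {key} appears in non-contiguous blocks")
        seen[key] = True
        curves.append(
            DeformabilityCurve(
                ss=group["shear_stress_pa"].to_numpy(),
                ei=group["ei"].to_numpy(),
                condition=str(condition),
                phase=str(phase),
                subject_id=str(subject),
                replicate=int(replicate),
            )
        )
    return curves


# --------------------------------------------------------------------------- #
# VTK legacy export
# --------------------------------------------------------------------------- #


def _fmt(arr) -> str:
    return "\n".join(" ".join(f"{v:.9e}" for v in row) for row in np.atleast_2d(arr))


def _write_vtk(path: Path, field, ei_fields=()) -> None:
    ny, nx = field.u.shape
    lines = [
        "# vtk DataFile Version 3.0",
        f"rbc_oxyshear flow field t={field.time:.9e} s",
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {nx} {ny} 1",
        f"POINTS {nx * ny} double",
    ]
    X, Y = np.meshgrid(field.x, field.y)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    lines.append(_fmt(pts))
    lines.append(f"POINT_DATA {nx * ny}")
    arrays = {
        "u": field.u,
        "v": field.v,
        "p": field.p,
        "gamma_dot": field.gamma_dot,
        "mu": field.mu,
        "tau": field.tau,
    }
    for ei_field in ei_fields:
        if ei_field.ei.shape != field.u.shape:
            raise GridMismatchError("EI field grid does not match the flow field")
        label = "ei_oxy" if ei_field.condition == "oxygenated" else "ei_deoxy"
        arrays[label] = ei_field.ei
    if "ei_oxy" in arrays and "ei_deoxy" in arrays:
        arrays["ei_diff"] = arrays["ei_deoxy"] - arrays["ei_oxy"]
    for name, arr in arrays.items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.append(_fmt(arr.ravel()[:, None]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def export_fields(fields, out_dir, ei_fields_by_phase=None) -> list[Path]:
    """Write one VTK legacy structured-grid file per stored phase.

    ``ei_fields_by_phase`` optionally maps phase index -> sequence of EIField
    to append as ``ei_oxy``/``ei_deoxy`` (+ ``ei_diff``) point data.

    Returns the written paths, in phase order (monotone time stamps).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fields = list(fields)
    paths = []
    for k, f in enumerate(fields):
        ei_fields = (ei_fields_by_phase or {}).get(k, ())
        p = out_dir / f"field_{k:04d}.vtk"
        _write_vtk(p, f, ei_fields)
        paths.append(p)
    return paths


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} must be a YAML mapping")
    return cfg
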