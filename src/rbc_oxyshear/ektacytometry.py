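"""Ektacytometry primitives: elongation index and deformability-curve parameterization.

A LORRCA-style ektacytometer shears a dilute RBC suspension in a Couette gap and
records the laser-diffraction pattern of the deforming cells.  The elongation
index ``EI = (a - b) / (a + b)`` of the elliptical pattern (vertical axis ``a``,
horizontal axis ``b``) quantifies cell deformation; a deformability curve is EI
measured at a ladder of applied shear stresses.  The curve is conventionally
summarized by the maximal elongation ``EI_max`` and the shear stress ``SS_1/2``
at which half of it is reached, obtained from the Lineweaver-Burke
linearization of the saturating hyperbola EI(SS) = EI_max * SS / (SS_1/2 + SS).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    GridMismatchError,
    InsufficientDataError,
    InvalidMeasurementError,
    NonPhysicalFitError,
)

#: Canonical LORRCA shear-stress ladder (Pa), 10 levels from 0.3 to 50 Pa.
CANONICAL_SS = np.array(
    [0.3, 0.53, 0.94, 1.65, 2.91, 5.15, 9.09, 16.04, 28.32, 50.0]
)

CONDITIONS = ("oxygenated", "deoxygenated")
PHASES = ("before_5Pa", "after_5Pa")


@dataclass(frozen=True)
class DiffractionMeasurement:
    """Axes of the elliptical diffraction pattern, in identical arbitrary units."""

    a: float  # vertical axis length, > 0
    b: float  # horizontal axis length, > 0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise InvalidMeasurementError(
                f"diffraction axes must be positive, got a={self.a}, b={self.b}"
            )

    @property
    def elongation_index(self) -> float:
        return (self.a - self.b) / (self.a + self.b)


def elongation_index(a, b=None):
    """Elongation index (a - b) / (a + b) of a diffraction pattern.

    Parameters
    ----------
    a : float, array-like, or DiffractionMeasurement
        Vertical axis length (or a full measurement, in which case `b` is ignored).
    b : float or array-like, optional
        Horizontal axis length.

    Returns
    -------
    float or ndarray
        Dimensionless EI in (-1, 1).  Zero iff a == b; antisymmetric under a<->b.
    """
    if isinstance(a, DiffractionMeasurement):
        return a.elongation_index
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise InvalidMeasurementError("diffraction axes must be positive")
    out = (a - b) / (a + b)
    return float(out) if out.ndim == 0 else out


@dataclass
class DeformabilityCurve:
    """Paired (shear stress, EI) observations for one measurement run.

    ``ss`` must be strictly increasing and positive; EI lies in (-1, 1)
    (negative values occur for fragmenting ghost membranes at high stress).
    """

    ss: np.ndarray  # shear stress, Pa
    ei: np.ndarray  # elongation index, dimensionless
    condition: str = "oxygenated"
    phase: str = "before_5Pa"
    subject_id: str = "S0"
    replicate: int = 1

    def __post_init__(self) -> None:
        self.ss = np.asarray(self.ss, dtype=float)
        self.ei = np.asarray(self.ei, dtype=float)
        if self.ss.shape != self.ei.shape or self.ss.ndim != 1:
            raise ValueError("ss and ei must be 1-D arrays of equal length")
        if np.any(self.ss <= 0):
            raise ValueError("shear stresses must be positive")
        if np.any(np.diff(self.ss) <= 0):
            raise ValueError("shear stresses must be strictly increasing")
        if np.any(np.abs(self.ei) >= 1):
            raise ValueError("EI must lie in (-1, 1)")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")

    def __len__(self) -> int:
        return len(self.ss)


@dataclass(frozen=True)
class LBParams:
    """Lineweaver-Burke parameterization of a deformability curve."""

    ei_max: float       # asymptotic maximal elongation, dimensionless
    ss_half: float      # shear stress at half-maximal elongation, Pa
    ratio: float        # ss_half / ei_max, Pa (normalized SS_1/2)
    r2_linear: float    # R^2 of the linearized (1/EI vs 1/SS) regression
    n_used: int         # points entering the regression after exclusions
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.ei_max > 0 and self.ss_half > 0):
            raise NonPhysicalFitError(
                f"ei_max and ss_half must be positive, got {self.ei_max}, {self.ss_half}"
            )


class LineweaverBurkeRegression(RegressorMixin, BaseEstimator):
    """Hyperbolic EI(SS) model fitted through the Lineweaver-Burke linearization.

    Ordinary least squares of 1/EI on 1/SS; EI_max = 1/intercept and
    SS_1/2 = slope/intercept.  Exact on noiseless hyperbolas.

    Parameters
    ----------
    exclusion_policy : {"positive_ei", "error"}
        How to treat points with EI <= 0 (ghost-fragmentation artifacts):
        drop them with a warning (default), or refuse to fit.
    weights : array-like or None
        Optional weights on the transformed regression; default unweighted.

    Attributes
    ----------
    ei_max_, ss_half_, ratio_ : float
        Fitted parameters (ratio_ = ss_half_ / ei_max_ exactly as stored).
    r2_linear_ : float
        R^2 of the linearized regression.
    n_used_, n_excluded_ : int
    """

    def __init__(self, exclusion_policy: str = "positive_ei", weights=None):
        self.exclusion_policy = exclusion_policy
        self.weights = weights

    def fit(self, X, y):
        ss = np.asarray(X, dtype=float).reshape(-1)
        ei = np.asarray(y, dtype=float).reshape(-1)
        if ss.shape != ei.shape:
            raise ValueError("X and y lengths differ")
        if np.any(ss <= 0):
            raise ValueError("shear stresses must be positive")

        usable = ei > 0
        n_excluded = int(np.sum(~usable))
        if n_excluded:
            if self.exclusion_policy == "error":
                raise InsufficientDataError(
                    f"{n_excluded} points with EI <= 0 and exclusion_policy='error'"
                )
            warnings.warn(
                f"excluded {n_excluded} points with EI <= 0 from Lineweaver-Burke fit",
                stacklevel=2,
            )
        ss, ei = ss[usable], ei[usable]
        if len(ss) < 3:
            raise InsufficientDataError(
                f"need >= 3 points with EI > 0, got {len(ss)}"
            )

        x, yy = 1.0 / ss, 1.0 / ei
        w = None if self.weights is None else np.asarray(self.weights, float)[usable]
        slope, intercept = np.polyfit(x, yy, 1, w=w)
        if intercept <= 0:
            raise NonPhysicalFitError(
                f"non-positive Lineweaver-Burke intercept ({intercept:.4g}); "
                "curve is not hyperbola-like"
            )
        yy_hat = slope * x + intercept
        ss_tot = np.sum((yy - yy.mean()) ** 2)
        self.r2_linear_ = float(1.0 - np.sum((yy - yy_hat) ** 2) / ss_tot) if ss_tot > 0 else 1.0
        self.ei_max_ = float(1.0 / intercept)
        self.ss_half_ = float(slope / intercept)
        if self.ss_half_ <= 0:
            raise NonPhysicalFitError(
                f"non-positive SS_1/2 ({self.ss_half_:.4g}) from Lineweaver-Burke fit"
            )
        self.ratio_ = self.ss_half_ / self.ei_max_
        self.n_used_ = int(len(ss))
        self.n_excluded_ = n_excluded
        return self

    def predict(self, X):
        ss = np.asarray(X, dtype=float).reshape(-1)
        return self.ei_max_ * ss / (self.ss_half_ + ss)


def lineweaver_burke_fit(
    curve: DeformabilityCurve, exclusion_policy: str = "positive_ei"
) -> LBParams:
    """Parameterize a deformability curve via the Lineweaver-Burke linearization."""
    est = LineweaverBurkeRegression(exclusion_policy=exclusion_policy)
    est.fit(curve.ss, curve.ei)
    return LBParams(
        ei_max=est.ei_max_,
        ss_half=est.ss_half_,
        ratio=est.ratio_,
        r2_linear=est.r2_linear_,
        n_used=est.n_used_,
        n_excluded=est.n_excluded_,
    )


def summarize_protocol(curves) -> pd.DataFrame:
    """Group means and standard errors per (condition, phase, SS level).

    Replicates of a subject are averaged first; the SE is then the cross-subject
    standard error (n-1 denominator).  With a single subject SE is reported as 0
    by convention.  All curves must share one SS grid.

    Returns a DataFrame with columns
    ``condition, phase, shear_stress_pa, n, mean_ei, se_ei``.
    """
    curves = list(curves)
    if not curves:
        raise InsufficientDataError("no curves to summarize")
    grid = curves[0].ss
    for c in curves[1:]:
        if len(c.ss) != len(grid) or not np.allclose(c.ss, grid):
            raise GridMismatchError("curves do not share a common SS grid")

    rows = []
    for c in curves:
        for s, e in zip(c.ss, c.ei):
            rows.append((c.condition, c.phase, c.subject_id, s, e))
    df = pd.DataFrame(
        rows, columns=["condition", "phase", "subject", "shear_stress_pa", "ei"]
    )
    per_subject = (
        df.groupby(["condition", "phase", "shear_stress_pa", "subject"], sort=True)[
            "ei"
        ]
        .mean()
        .reset_index()
    )
    out = (
        per_subject.groupby(["condition", "phase", "shear_stress_pa"], sort=True)["ei"]
        .agg(n="count", mean_ei="mean", se_ei=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
        .reset_index()
    )
    out["se_ei"] = out["se_ei"].fillna(0.0)
    return out
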