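"""Casson constitutive law for whole blood with hematocrit-dependent parameters.

Blood is shear-thinning with a small yield stress.  The Casson model writes the
apparent viscosity for shear rate gamma_dot > 0 as

    mu(gamma_dot) = (sqrt(tau_y / gamma_dot) + sqrt(mu_c))^2
                  = tau_y/gamma_dot + 2*sqrt(tau_y*mu_c/gamma_dot) + mu_c

where tau_y = mu_inf^2 is the yield stress (Pa) and mu_c = n_inf^2 the
infinite-shear (Casson) viscosity (Pa*s).  At non-positive shear rate the
nominal blood viscosity 0.0035 Pa*s is used as a fallback, and an optional cap
bounds the viscosity near stagnation.

Both Casson parameters depend on hematocrit.  Two parameterizations are kept:

* ``literal``    -- mu_inf = 0.625 * Hct (sqrt-Pa), as printed in the source
  rheology literature for this model;
* ``calibrated`` -- mu_inf = sqrt(0.1 * (0.625 * Hct)^3), a cubic yield-stress
  law under which the default viscosity cap 2.072e-2 Pa*s is reached at a
  plausible near-stagnation shear rate (~0.15 1/s).

In both, n_inf = sqrt(mu0) * (1 - Hct)^(-0.25), so the infinite-shear viscosity
is mu0 * (1 - Hct)^(-0.5) -- about 1.87e-3 Pa*s at Hct 0.4 with plasma
viscosity 1.45e-3 Pa*s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

#: Nominal whole-blood viscosity used when the shear rate vanishes (Pa*s).
MU_FALLBACK_DEFAULT = 0.0035
#: Default viscosity cap near stagnation (Pa*s).
MU_CAP_DEFAULT = 2.072e-2


@dataclass(frozen=True)
class CassonParams:
    """Inputs of the Casson law.

    Parameters
    ----------
    hct : float
        Hematocrit volume fraction, in (0, 1).  Default 0.4.
    mu0 : float
        Plasma viscosity, Pa*s.  Default 1.45e-3.
    mu_fallback : float
        Viscosity returned at non-positive shear rate, Pa*s.
    mu_cap : float or None
        Upper bound on the apparent viscosity (None disables the cap).
    preset : {"literal", "calibrated"}
        Yield-stress parameterization (see module docstring).
    """

    hct: float = 0.4
    mu0: float = 1.45e-3
    mu_fallback: float = MU_FALLBACK_DEFAULT
    mu_cap: float | None = MU_CAP_DEFAULT
    preset: str = "literal"

    def __post_init__(self) -> None:
        if not (0.0 < self.hct < 1.0):
            raise ConfigurationError(f"hematocrit must be in (0, 1), got {self.hct}")
        if self.mu0 <= 0 or self.mu_fallback <= 0:
            raise ConfigurationError("mu0 and mu_fallback must be positive")
        if self.mu_cap is not None and self.mu_cap < self.mu_fallback:
            raise ConfigurationError("mu_cap must be >= mu_fallback when set")
        if self.preset not in ("literal", "calibrated"):
            raise ConfigurationError(f"unknown preset {self.preset!r}")


@dataclass(frozen=True)
class CassonDerived:
    """Derived Casson coefficients: all strictly positive."""

    n_inf: float          # sqrt-Casson viscosity, (Pa*s)^0.5
    mu_inf: float         # sqrt-Casson yield stress, Pa^0.5
    yield_stress: float   # tau_y = mu_inf^2, Pa
    mu_high_shear: float  # mu_c = n_inf^2, infinite-shear viscosity, Pa*s


def derive_params(p: CassonParams) -> CassonDerived:
    """Hematocrit-dependent Casson coefficients for either parameterization."""
    n_inf = np.sqrt(p.mu0) * (1.0 - p.hct) ** (-0.25)
    if p.preset == "literal":
        mu_inf = 0.625 * p.hct
    else:  # calibrated
        mu_inf = np.sqrt(0.1 * (0.625 * p.hct) ** 3)
    return CassonDerived(
        n_inf=float(n_inf),
        mu_inf=float(mu_inf),
        yield_stress=float(mu_inf**2),
        mu_high_shear=float(n_inf**2),
    )


def apparent_viscosity(gamma_dot, p: CassonParams):
    """Casson apparent viscosity (Pa*s) at shear rate gamma_dot (1/s).

    Piecewise: the Casson expression for gamma_dot > 0, the fallback
    otherwise; finally capped at ``p.mu_cap`` when set.  Continuous and
    strictly decreasing in gamma_dot on (0, inf) before capping.
    """
    gamma_dot = np.asarray(gamma_dot, dtype=float)
    d = derive_params(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        casson = (np.sqrt(d.yield_stress / np.maximum(gamma_dot, 1e-300))
                  + np.sqrt(d.mu_high_shear)) ** 2
    mu = np.where(gamma_dot > 0, casson, p.mu_fallback)
    if p.mu_cap is not None:
        mu = np.minimum(mu, p.mu_cap)
    return float(mu) if mu.ndim == 0 else mu


def casson_shear_rate_from_stress(tau, p: CassonParams):
    """Invert the (optionally capped) Casson law: shear rate (1/s) at stress tau (Pa).

    For the uncapped law the inversion is sqrt(tau) = sqrt(tau_y) +
    sqrt(mu_c * gamma_dot), with gamma_dot = 0 inside the plug (tau <= tau_y).
    With a viscosity cap the low-stress branch is Newtonian at mu_cap, so the
    plug is replaced by slow creep; the two branches join continuously.
    """
    tau = np.asarray(tau, dtype=float)
    d = derive_params(p)
    sqrt_ty = np.sqrt(d.yield_stress)
    mu_c = d.mu_high_shear
    # Uncapped Casson branch (zero inside the plug).
    gd = np.where(tau > d.yield_stress, (np.sqrt(np.maximum(tau, 0.0)) - sqrt_ty) ** 2 / mu_c, 0.0)
    if p.mu_cap is not None and p.mu_cap > mu_c:
        # Capped-branch crossover: below tau_star the material is Newtonian at mu_cap.
        gd_star = d.yield_stress / (np.sqrt(p.mu_cap) - np.sqrt(mu_c)) ** 2
        tau_star = p.mu_cap * gd_star
        gd = np.where(tau <= tau_star, tau / p.mu_cap, gd)
    return float(gd) if gd.ndim == 0 else gd


def shear_rate(grad_u) -> float:
    """Scalar shear rate sqrt(2 D:D) from a velocity-gradient tensor (1/s entries).

    D = (grad_u + grad_u^T) / 2.  Frame-consistent: invariant under rigid
    rotations of the tensor.  Accepts 2x2 or 3x3 arrays.
    """
    g = np.asarray(grad_u, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1] or g.shape[0] not in (2, 3):
        raise ValueError(f"expected a 2x2 or 3x3 tensor, got shape {g.shape}")
    d = 0.5 * (g + g.T)
    return float(np.sqrt(2.0 * np.sum(d * d)))
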