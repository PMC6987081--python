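"""Synthetic LORRCA-like deformability datasets with known ground truth.

The generator emulates the measurement design of the study conditions: 10
subjects, two replicate runs each, EI recorded at the canonical 10-level
shear-stress ladder under four conditions (oxygenated/deoxygenated crossed
with before/after a 5 Pa x 300 s conditioning exposure).  The generative
model is

    EI(ss) = truth_condition(ss)
             + 1{phase = after, ss <= 1.65 Pa} * after_ss_effect
             + b_subject + noise

with the condition truths given by the built-in calibration presets, a shared
per-subject random intercept b_s ~ N(0, subject_sd^2), and i.i.d. Gaussian
measurement noise.  The conditioning effect is additive only at the low-stress
levels (0.3-1.65 Pa) where the protocol measurably improves deformability.

Ghost curves (resealed hemoglobin-free membranes) are generated separately:
they elongate normally up to ~3 Pa, then fragment under higher stress and the
apparent EI decreases, crossing below zero above 5.15 Pa.  They exercise the
exclusion and misfit error paths of the fitting routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import PRESETS, ExpCalibration, evaluate
from .ektacytometry import CANONICAL_SS, DeformabilityCurve
from .errors import ConfigurationError


@dataclass
class SynthConfig:
    """Generator settings; defaults reproduce the study's measurement design."""

    n_subjects: int = 10
    n_replicates: int = 2
    ss_grid: np.ndarray = field(default_factory=lambda: CANONICAL_SS.copy())
    truth_oxy: ExpCalibration = field(
        default_factory=lambda: PRESETS["eq1_oxygenated"]
    )
    truth_deoxy: ExpCalibration = field(
        default_factory=lambda: PRESETS["eq2_deoxygenated"]
    )
    after_ss_effect: float = 0.01   # additive EI shift at SS <= 1.65 Pa, after phase
    after_ss_threshold: float = 1.65  # Pa
    subject_sd: float = 0.01        # between-subject SD of EI
    noise_sd: float = 0.005         # within-measurement SD of EI
    seed: int = 0

    def __post_init__(self):
        self.ss_grid = np.asarray(self.ss_grid, dtype=float)
        if self.n_subjects < 1 or self.n_replicates < 1:
            raise ConfigurationError("need at least one subject and one replicate")
        if self.subject_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        for truth in (self.truth_oxy, self.truth_deoxy):
            mean_hi = evaluate(truth, self.ss_grid) + abs(self.after_ss_effect)
            mean_lo = evaluate(truth, self.ss_grid) - abs(self.after_ss_effect)
            if np.any(mean_hi >= 1.0) or np.any(mean_lo <= 0.0):
                raise ConfigurationError(
                    "after_ss_effect pushes a mean EI outside (0, 1)"
                )


def generate_dataset(cfg: SynthConfig) -> list[DeformabilityCurve]:
    """Draw the full synthetic design: subjects x conditions x phases x replicates.

    Bit-reproducible from ``cfg.seed``; 10*2*2*2 = 80 curves at defaults.
    EI values are clipped to (-0.999, 0.999) only as a last-resort guard
    (the config validation keeps means well inside (0, 1)).
    """
    rng = np.random.default_rng(cfg.seed)
    b_subject = rng.normal(0.0, cfg.subject_sd, size=cfg.n_subjects)
    truths = {"oxygenated": cfg.truth_oxy, "deoxygenated": cfg.truth_deoxy}
    curves = []
    for s in range(cfg.n_subjects):
        for condition in ("oxygenated", "deoxygenated"):
            base = evaluate(truths[condition], cfg.ss_grid)
            for phase in ("before_5Pa", "after_5Pa"):
                shift = np.where(
                    (phase == "after_5Pa") & (cfg.ss_grid <= cfg.after_ss_threshold),
                    cfg.after_ss_effect,
                    0.0,
                )
                for rep in range(1, cfg.n_replicates + 1):
                    noise = rng.normal(0.0, cfg.noise_sd, size=len(cfg.ss_grid))
                    ei = np.clip(base + shift + b_subject[s] + noise, -0.999, 0.999)
                    curves.append(
                        DeformabilityCurve(
                            ss=cfg.ss_grid.copy(),
                            ei=ei,
                            condition=condition,
                            phase=phase,
                            subject_id=f"S{s + 1:02d}",
                            replicate=rep,
                        )
                    )
    return curves


def _ghost_truth(ss: np.ndarray) -> np.ndarray:
    # Rises hyperbolically to ~0.3 by ~3 Pa, then fragmentation drags the
    # apparent EI down, crossing zero between 5.15 and 9.09 Pa.
    return 0.36 * ss / (0.5 + ss) - 0.5 / (1.0 + np.exp(-(ss - 7.0) / 1.5))


def generate_ghost_curves(cfg: SynthConfig) -> list[DeformabilityCurve]:
    """Ghost-membrane curves: positive at low stress, negative above 5.15 Pa."""
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    curves = []
    for s in range(cfg.n_subjects):
        base = _ghost_truth(cfg.ss_grid)
        for condition in ("oxygenated", "deoxygenated"):
            for rep in range(1, cfg.n_replicates + 1):
                noise = rng.normal(0.0, cfg.noise_sd, size=len(cfg.ss_grid))
                ei = np.clip(base + noise, -0.999, 0.999)
                curves.append(
                    DeformabilityCurve(
                        ss=cfg.ss_grid.copy(),
                        ei=ei,
                        condition=condition,
                        phase="before_5Pa",
                        subject_id=f"G{s + 1:02d}",
                        replicate=rep,
                    )
                )
    return curves
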