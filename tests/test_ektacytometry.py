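import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbc_oxyshear.ektacytometry import (
    CANONICAL_SS,
    DeformabilityCurve,
    DiffractionMeasurement,
    LineweaverBurkeRegression,
    elongation_index,
    lineweaver_burke_fit,
    summarize_protocol,
)
from rbc_oxyshear.errors import (
    GridMismatchError,
    InsufficientDataError,
    InvalidMeasurementError,
    NonPhysicalFitError,
)


def hyperbola_curve(ei_max=0.6, ss_half=2.0, ss=None, **kw):
    ss = CANONICAL_SS if ss is None else np.asarray(ss, float)
    return DeformabilityCurve(ss=ss, ei=ei_max * ss / (ss_half + ss), **kw)


class TestElongationIndex:
    @pytest.mark.parametrize(
        "a,b,expected", [(2.0, 2.0, 0.0), (3.0, 1.0, 0.5), (1.0, 3.0, -0.5)]
    )
    def test_reference_values(self, a, b, expected):
        assert elongation_index(a, b) == pytest.approx(expected, abs=1e-15)
        assert DiffractionMeasurement(a, b).elongation_index == pytest.approx(expected)

    @given(
        a=st.floats(0.01, 1e3, allow_nan=False),
        b=st.floats(0.01, 1e3, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        ei = elongation_index(a, b)
        assert -1.0 < ei < 1.0
        assert ei == pytest.approx(-elongation_index(b, a), abs=1e-15)
        if a == b:
            assert ei == 0.0

    def test_nonpositive_axis_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            elongation_index(0.0, 1.0)
        with pytest.raises(InvalidMeasurementError):
            DiffractionMeasurement(1.0, -2.0)


class TestLineweaverBurke:
    def test_exact_on_noiseless_hyperbola(self):
        lb = lineweaver_burke_fit(hyperbola_curve())
        assert lb.ei_max == pytest.approx(0.6, rel=1e-10)
        assert lb.ss_half == pytest.approx(2.0, rel=1e-10)
        assert lb.ratio == pytest.approx(2.0 / 0.6, rel=1e-10)
        assert lb.r2_linear == pytest.approx(1.0, abs=1e-12)
        assert lb.n_used == 10

    @given(
        ei_max=st.floats(0.05, 0.95),
        ss_half=st.floats(0.1, 20.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_exact_recovery_property(self, ei_max, ss_half):
        lb = lineweaver_burke_fit(hyperbola_curve(ei_max, ss_half))
        assert lb.ei_max == pytest.approx(ei_max, rel=1e-9)
        assert lb.ss_half == pytest.approx(ss_half, rel=1e-9)
        # ratio is stored as the exact quotient of the stored fields
        assert lb.ratio == lb.ss_half / lb.ei_max

    def test_negative_point_excluded_with_warning(self):
        c = hyperbola_curve()
        ei = c.ei.copy()
        ei[7] = -0.1
        curve = DeformabilityCurve(ss=c.ss, ei=ei)
        with pytest.warns(UserWarning, match="excluded 1 points"):
            lb = lineweaver_burke_fit(curve)
        assert lb.n_used == 9
        assert lb.n_excluded == 1
        assert lb.ei_max == pytest.approx(0.6, rel=1e-10)
        assert lb.ss_half == pytest.approx(2.0, rel=1e-10)

    def test_order_invariance(self):
        ss = CANONICAL_SS
        ei = 0.55 * ss / (3.0 + ss)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ss))
        a = LineweaverBurkeRegression().fit(ss, ei)
        b = LineweaverBurkeRegression().fit(ss[perm], ei[perm])
        assert a.ei_max_ == pytest.approx(b.ei_max_, rel=1e-12)
        assert a.ss_half_ == pytest.approx(b.ss_half_, rel=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            lineweaver_burke_fit(
                DeformabilityCurve(ss=[1.0, 2.0], ei=[0.2, 0.3])
            )

    def test_non_hyperbolic_curve_raises(self):
        # decreasing 1/EI vs 1/SS with negative intercept
        ss = np.array([1.0, 2.0, 4.0, 8.0])
        ei = np.array([0.6, 0.3, 0.15, 0.075])  # EI ~ 1/SS => intercept ~ 0/negative
        with pytest.raises(NonPhysicalFitError):
            lineweaver_burke_fit(DeformabilityCurve(ss=ss, ei=ei))

    def test_monte_carlo_recovery(self):
        """Mean recovered EI_max within 0.02 of truth at sigma = 0.005."""
        rng = np.random.default_rng(12345)
        base = hyperbola_curve()
        est = []
        for _ in range(200):
            ei = base.ei + rng.normal(0.0, 0.005, base.ei.size)
            lb = lineweaver_burke_fit(DeformabilityCurve(ss=base.ss, ei=ei))
            est.append(lb.ei_max)
        assert abs(np.mean(est) - 0.6) < 0.02


class TestSummarizeProtocol:
    def test_single_curve_means(self):
        c = hyperbola_curve(subject_id="S1")
        out = summarize_protocol([c])
        assert np.allclose(np.sort(out["mean_ei"].to_numpy()), np.sort(c.ei))
        assert (out["se_ei"] == 0.0).all()
        assert (out["n"] == 1).all()

    def test_identical_subjects_zero_se(self):
        a = hyperbola_curve(subject_id="S1")
        b = hyperbola_curve(subject_id="S2")
        out = summarize_protocol([a, b])
        assert (out["n"] == 2).all()
        assert np.allclose(out["se_ei"], 0.0)

    def test_replicates_averaged_before_se(self):
        # two replicates of one subject offset by +/-d: subject mean is exact,
        # so the cross-subject SE must not see the replicate spread
        base = hyperbola_curve(subject_id="S1", replicate=1)
        up = DeformabilityCurve(ss=base.ss, ei=base.ei + 0.02, subject_id="S1", replicate=2)
        down = DeformabilityCurve(ss=base.ss, ei=base.ei - 0.02, subject_id="S1", replicate=1)
        other = hyperbola_curve(subject_id="S2")
        out = summarize_protocol([up, down, other])
        assert (out["n"] == 2).all()
        assert np.allclose(out["se_ei"], 0.0, atol=1e-14)

    def test_grid_mismatch_raises(self):
        a = hyperbola_curve()
        b = hyperbola_curve(ss=[0.5, 1.0, 2.0, 4.0, 8.0])
        with pytest.raises(GridMismatchError):
            summarize_protocol([a, b])

    def test_means_track_truth_within_3se(self):
        from rbc_oxyshear.calibration import evaluate, get_preset
        from rbc_oxyshear.synth import SynthConfig, generate_dataset

        hits = total = 0
        for seed in range(5):
            curves = generate_dataset(SynthConfig(seed=seed))
            out = summarize_protocol(curves)
            before = out[(out["phase"] == "before_5Pa")]
            for condition, preset in (
                ("oxygenated", "eq1_oxygenated"),
                ("deoxygenated", "eq2_deoxygenated"),
            ):
                sub = before[before["condition"] == condition]
                truth = evaluate(get_preset(preset), sub["shear_stress_pa"].to_numpy())
                se = np.maximum(sub["se_ei"].to_numpy(), 1e-12)
                hits += int(np.sum(np.abs(sub["mean_ei"].to_numpy() - truth) <= 3 * se))
                total += len(sub)
        assert hits / total >= 0.95
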