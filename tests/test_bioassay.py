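"""Orientation analysis, ΔΔCt quantification, Grubbs screening, t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import rotate

from diadflow.bioassay import (
    DegenerateImageError,
    delta_delta_ct,
    grubbs_critical_value,
    grubbs_test,
    make_fixtures,
    orientation_histogram,
    significance_stars,
    two_sample_ttest,
)


class TestOrientation:
    @pytest.mark.parametrize("angle", [30.0, -60.0, 0.0, 75.0])
    def test_recovers_stripe_angle(self, angle):
        img = make_fixtures("stripes", {"angle_deg": angle})
        hist = orientation_histogram(img)
        diff = (hist.dominant_angle - angle + 90) % 180 - 90
        assert abs(diff) <= 2.0

    def test_rotation_equivariance(self):
        # scipy's rotate turns the array counterclockwise in (row, col)
        # display coordinates, which is clockwise in the x-right/y-down-as-up
        # convention used here: the measured angle shifts by −rotation.
        img = make_fixtures("stripes", {"angle_deg": 30.0})
        rotated = rotate(img, -45.0, reshape=False, mode="reflect")
        hist = orientation_histogram(rotated[10:-10, 10:-10])
        diff = (hist.dominant_angle - 75.0 + 90) % 180 - 90
        assert abs(diff) <= 2.0

    def test_noise_image_is_near_uniform(self):
        rng = np.random.default_rng(0)
        img = rng.standard_normal((256, 256))
        hist = orientation_histogram(img)
        assert hist.weights.max() < 2.0 * hist.weights.mean()

    def test_weights_normalized(self):
        img = make_fixtures("stripes", {"angle_deg": 10.0, "noise": 0.2})
        hist = orientation_histogram(img)
        assert hist.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(hist.weights >= 0)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            orientation_histogram(np.full((64, 64), 0.5))

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            orientation_histogram(np.zeros((32, 32)))

    def test_aligned_monolayer_has_low_dispersion(self):
        aligned = orientation_histogram(make_fixtures("stripes", {"angle_deg": 20.0}))
        rng = np.random.default_rng(1)
        noisy = orientation_histogram(rng.standard_normal((256, 256)))
        assert aligned.dispersion < noisy.dispersion


class TestDeltaDeltaCt:
    def test_control_group_fold_change_is_one(self):
        table = make_fixtures("ct_table", {"genes": {"KLF2": -1.0}})
        out = delta_delta_ct(table, "KLF2")
        static = out[out.group == "static"]
        assert static.fold_change.to_numpy() == pytest.approx(np.ones(len(static)))

    def test_one_cycle_shift_doubles_expression(self):
        table = make_fixtures("ct_table", {"genes": {"KLF2": -1.0}})
        out = delta_delta_ct(table, "KLF2")
        flow = out[out.group == "flow"]
        assert flow.fold_change.to_numpy() == pytest.approx(np.full(len(flow), 2.0))

    def test_hand_computed_example(self):
        table = pd.DataFrame(
            {
                "sample": ["c1", "c1", "t1", "t1"],
                "group": ["static", "static", "flow", "flow"],
                "gene": ["GAPDH", "eNOS", "GAPDH", "eNOS"],
                "ct": [18.0, 24.0, 18.0, 23.0],
            }
        )
        out = delta_delta_ct(table, "eNOS")
        t1 = out[out["sample"] == "t1"].iloc[0]
        assert t1.ddct == pytest.approx(-1.0)
        assert t1.fold_change == pytest.approx(2.0)

    def test_technical_replicates_averaged_on_ct(self):
        table = pd.DataFrame(
            {
                "sample": ["c1"] * 3 + ["t1"] * 2,
                "group": ["static"] * 3 + ["flow"] * 2,
                "gene": ["GAPDH", "eNOS", "eNOS", "GAPDH", "eNOS"],
                "ct": [18.0, 23.5, 24.5, 18.0, 23.0],  # replicates mean 24
            }
        )
        out = delta_delta_ct(table, "eNOS")
        assert out[out["sample"] == "t1"].fold_change.iloc[0] == pytest.approx(2.0)

    def test_missing_gene_or_group_rejected(self):
        table = make_fixtures("ct_table", {"genes": {"KLF2": -1.0}})
        with pytest.raises(ValueError):
            delta_delta_ct(table, "MCP1")
        with pytest.raises(ValueError):
            delta_delta_ct(table, "KLF2", control_group="mock")


class TestGrubbs:
    def test_flags_planted_outlier(self):
        # G = 1.499 exceeds the n=4 critical value 1.481 at α = 0.05
        assert grubbs_test([0.9, 1.0, 1.1, 5.0], alpha=0.05) == 3
        assert grubbs_critical_value(4, 0.05) == pytest.approx(1.481, abs=2e-3)

    def test_symmetric_sample_clean(self):
        assert grubbs_test([-2, -1, 0, 1, 2]) is None

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            grubbs_test([1.0, 1.0, 1.0])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            grubbs_test([1.0, 2.0])

    def test_near_equal_values_never_flagged(self):
        assert grubbs_test([1.0, 1.0 + 1e-9, 1.0 - 1e-9]) is None


class TestTTest:
    def test_identical_samples(self):
        t, p = two_sample_ttest([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pooled_t(self):
        t, p = two_sample_ttest([1, 2, 3, 4], [3, 4, 5, 6])
        assert t == pytest.approx(-2.191, abs=1e-3)
        assert p == pytest.approx(0.0707, abs=1e-3)

    def test_antisymmetry(self):
        t1, p1 = two_sample_ttest([1, 2, 3, 4], [3, 4, 5, 6])
        t2, p2 = two_sample_ttest([3, 4, 5, 6], [1, 2, 3, 4])
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_degenerate_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0, 1.0], [2.0, 2.0])

    def test_p_value_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a = rng.normal(0, 1, 5)
            b = rng.normal(0.5, 1, 5)
            _, p = two_sample_ttest(a, b)
            assert 0 < p <= 1

    def test_stars(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == "ns"


class TestFixtures:
    def test_deterministic_for_fixed_seed(self):
        a = make_fixtures("stripes", {"angle_deg": 30.0, "noise": 0.1}, seed=5)
        b = make_fixtures("stripes", {"angle_deg": 30.0, "noise": 0.1}, seed=5)
        assert np.array_equal(a, b)
        t1 = make_fixtures("ct_table", {"noise": 0.2}, seed=5)
        t2 = make_fixtures("ct_table", {"noise": 0.2}, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_fixtures("chromatograms", {})

    def test_wss_series_reversal_osi_known(self):
        from diadflow.shear import compute_profile

        s = make_fixtures("wss_series", {"reversal_fraction": 0.1})
        profile = compute_profile(s)
        assert profile.osi == pytest.approx(np.full_like(profile.osi, 0.2))
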