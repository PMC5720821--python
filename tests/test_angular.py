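"""Quadrants, rose histograms, unification, ratios, symmetry calls,
angular correction and the group t-test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myoflow import angular, synth
from myoflow.angular import (AngularDataset, angular_correction,
                             assign_quadrant, classify_symmetry,
                             compare_groups, dominant_direction_ratio,
                             quadrant_fractions, ratio_bin,
                             retrograde_fraction, rose_histogram,
                             significance_stars, unify_to_up, weighted_ratio)
from myoflow.errors import ConfigurationError
from myoflow.geometry import circular_mean, circular_variance

angle_lists = st.lists(
    st.floats(0, 360, exclude_max=True, allow_nan=False), min_size=1,
    max_size=200)


def make_dataset(angles, cell_id=1, chamber_id=0, rotation="Up"):
    return AngularDataset(pd.DataFrame({
        "angle_deg": np.asarray(angles, float), "cell_id": cell_id,
        "chamber_id": chamber_id, "rotation_direction": rotation}))


class TestQuadrants:
    @pytest.mark.parametrize("angle,quadrant", [
        (90.0, "Up"), (270.0, "Down"), (0.0, "Anterior"), (180.0, "Posterior"),
        # half-open boundary rule: the boundary belongs to the quadrant it opens
        (45.0, "Up"), (135.0, "Posterior"), (225.0, "Down"),
        (315.0, "Anterior"), (44.999, "Anterior"), (314.999, "Down"),
        (224.999, "Posterior"),
    ])
    def test_quadrant_assignment(self, angle, quadrant):
        assert assign_quadrant(angle) == quadrant

    def test_out_of_range_rejected(self):
        for bad in (-1.0, 360.0, 400.0):
            with pytest.raises(ConfigurationError):
                assign_quadrant(bad)

    @given(angle_lists)
    def test_fractions_sum_to_one(self, angles):
        frac = quadrant_fractions(angles)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)

    @given(angle_lists)
    def test_quadrants_nest_five_degree_rose_bins(self, angles):
        # quadrant boundaries (45/135/225/315) fall on 5°-bin edges
        frac = quadrant_fractions(angles)
        rose = rose_histogram(angles, bin_width=5.0).to_numpy()
        lows = np.arange(72) * 5.0
        up = rose[(lows >= 45) & (lows < 135)].sum()
        post = rose[(lows >= 135) & (lows < 225)].sum()
        down = rose[(lows >= 225) & (lows < 315)].sum()
        ant = rose[(lows >= 315) | (lows < 45)].sum()
        assert frac["Up"] == pytest.approx(up, abs=1e-12)
        assert frac["Posterior"] == pytest.approx(post, abs=1e-12)
        assert frac["Down"] == pytest.approx(down, abs=1e-12)
        assert frac["Anterior"] == pytest.approx(ant, abs=1e-12)


class TestRoseHistogram:
    def test_single_bin_concentration(self):
        rose = rose_histogram(np.full(50, 10.0))
        assert rose.iloc[0] == 1.0 and rose.iloc[1:].sum() == 0.0

    def test_twenty_degree_bins_are_18(self):
        assert len(rose_histogram([10.0])) == 18

    def test_integer_sweep_counting_oracle(self):
        rose = rose_histogram(np.arange(360.0))
        np.testing.assert_allclose(rose.to_numpy(), 20.0 / 360.0)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ConfigurationError, match="divide 360"):
            rose_histogram([10.0], bin_width=50.0)


class TestUnification:
    def test_up_chamber_is_identity(self):
        ds = make_dataset([10.0, 200.0, 300.0], rotation="Up")
        out = unify_to_up(ds)
        np.testing.assert_array_equal(out.events.angle_deg,
                                      ds.events.angle_deg)

    def test_down_chamber_reflects_270_to_90(self):
        ds = make_dataset([270.0], rotation="Down")
        assert unify_to_up(ds).events.angle_deg.iloc[0] == 90.0

    @given(angle_lists)
    def test_reflection_is_an_involution(self, angles):
        reflected = (360.0 - np.asarray(angles)) % 360.0
        twice = (360.0 - reflected) % 360.0
        np.testing.assert_allclose(twice, np.asarray(angles) % 360.0,
                                   atol=1e-9)

    def test_reflection_preserves_ap_and_swaps_up_down(self, rng):
        angles = rng.uniform(0, 360, 500)
        before = quadrant_fractions(angles)
        ds = make_dataset(angles, rotation="Down")
        after = quadrant_fractions(unify_to_up(ds).events.angle_deg)
        assert after["Anterior"] == pytest.approx(before["Anterior"])
        assert after["Posterior"] == pytest.approx(before["Posterior"])
        assert after["Up"] == pytest.approx(before["Down"])
        assert after["Down"] == pytest.approx(before["Up"])

    def test_unknown_rotation_error_lists_chambers(self):
        ev = pd.concat([make_dataset([10.0], chamber_id=0).events,
                        make_dataset([10.0], chamber_id=7,
                                     rotation="unknown").events])
        with pytest.raises(ConfigurationError, match="7"):
            unify_to_up(AngularDataset(ev))


class TestRetrogradeFraction:
    def test_all_down_events_give_fraction_one(self):
        per, pooled = retrograde_fraction(make_dataset(np.full(30, 270.0)))
        assert pooled == 1.0 and per.iloc[0] == 1.0

    def test_equals_brute_force_count(self, rng):
        angles = rng.uniform(0, 360, 400)
        chambers = rng.integers(0, 4, 400)
        ds = AngularDataset(pd.DataFrame({
            "angle_deg": angles, "cell_id": 1, "chamber_id": chambers,
            "rotation_direction": "Up"}))
        per, pooled = retrograde_fraction(ds)
        for ch in range(4):
            sub = angles[chambers == ch]
            brute = np.mean((sub >= 225) & (sub < 315))
            assert per[ch] == pytest.approx(brute)
        assert pooled == pytest.approx(per.mean())

    def test_requires_unified_dataset(self):
        with pytest.raises(ConfigurationError, match="unified"):
            retrograde_fraction(make_dataset([270.0], rotation="Down"))


class TestWeightedRatio:
    def as_dataset(self, up, down, anterior=0):
        angles = ([90.0] * up) + ([270.0] * down) + ([0.0] * anterior)
        return make_dataset(angles)

    def test_balanced_counts_give_unit_ratio(self):
        rec = weighted_ratio(self.as_dataset(up=5, down=5)).iloc[0]
        assert rec.ratio == 1.0 and rec.log2_ratio == 0.0

    def test_nine_to_three_is_ratio_three_in_top_bin(self):
        rec = weighted_ratio(self.as_dataset(up=3, down=9)).iloc[0]
        assert rec.ratio == pytest.approx(3.0)
        assert rec.log2_ratio == pytest.approx(np.log2(3), abs=1e-9)
        assert rec.bin == ">3"  # log2(3) = 1.585, at the paper's >1.6 border

    def test_zero_anterograde_uses_half_pseudocount(self):
        rec = weighted_ratio(self.as_dataset(up=0, down=9)).iloc[0]
        assert rec.ratio == pytest.approx(19.0)  # (9 + 1/2) / (0 + 1/2)

    def test_anterior_posterior_events_excluded_but_counted(self):
        rec = weighted_ratio(self.as_dataset(up=2, down=4, anterior=7)).iloc[0]
        assert rec.retro_count == 4 and rec.antero_count == 2
        assert rec.other_count == 7
        assert rec.ratio == pytest.approx(2.0)

    def test_cell_without_axis_events_flagged_excluded(self):
        rec = weighted_ratio(self.as_dataset(up=0, down=0, anterior=5)).iloc[0]
        assert rec.excluded and np.isnan(rec.ratio)

    @pytest.mark.parametrize("ratio,label", [
        (0.5, "<1"), (1.0, "1-2"), (1.99, "1-2"), (2.0, "2-3"),
        (3.0, ">3"), (19.0, ">3")])
    def test_half_open_bins(self, ratio, label):
        assert ratio_bin(ratio) == label

    def test_chamber_summary_is_event_count_weighted(self):
        ev = pd.concat([
            make_dataset([90.0] * 1 + [270.0] * 2, cell_id=1).events,
            make_dataset([90.0] * 10 + [270.0] * 40, cell_id=2).events])
        out = weighted_ratio(AngularDataset(ev))
        w = out.retro_count + out.antero_count
        expected = np.average(out.log2_ratio, weights=w)
        assert out.attrs["chamber_summary"][0] == pytest.approx(expected)


class TestDominantDirection:
    def test_dominant_up_chamber_cell_ratio(self):
        ev = pd.concat([
            make_dataset([90.0] * 7 + [270.0] * 3, cell_id=1,
                         rotation="unknown").events,
            make_dataset([90.0] * 63 + [270.0] * 27, cell_id=2,
                         rotation="unknown").events])
        out = dominant_direction_ratio(AngularDataset(ev))
        assert (out.dominant == "Up").all()
        cell1 = out[out.cell_id == 1].iloc[0]
        assert cell1.ratio == pytest.approx(7 / 3)

    def test_exact_tie_flagged_and_defaults_to_up(self):
        ds = make_dataset([90.0] * 5 + [270.0] * 5, rotation="unknown")
        out = dominant_direction_ratio(ds)
        assert out.attrs["tied_chambers"] == [0]
        assert out.iloc[0].tie and out.iloc[0].dominant == "Up"

    def test_single_cell_chamber_matches_weighted_ratio_up_to_orientation(
            self, rng):
        angles = rng.uniform(0, 360, 200)
        static = dominant_direction_ratio(
            make_dataset(angles, rotation="unknown")).iloc[0]
        rotating = weighted_ratio(make_dataset(angles)).iloc[0]
        assert static.ratio == pytest.approx(
            max(rotating.ratio, 1.0 / rotating.ratio))


class TestSymmetryClassification:
    def test_balanced_large_sample_is_symmetric(self):
        assert classify_symmetry(100, 100)["label"] == "symmetric"

    def test_eighty_twenty_is_strong(self):
        res = classify_symmetry(80, 20)
        assert res["label"] == "strong asymmetry"
        # exact binomial oracle: P(|X - 50| >= 30), X ~ Bin(100, 1/2)
        from scipy.stats import binom
        p_oracle = binom.cdf(20, 100, 0.5) + binom.sf(79, 100, 0.5)
        assert res["p_value"] == pytest.approx(p_oracle, rel=1e-6)

    def test_moderate_imbalance_is_weak(self):
        res = classify_symmetry(65, 35)
        assert res["label"] == "weak asymmetry"

    def test_insufficient_events_rejected(self):
        with pytest.raises(ConfigurationError, match="insufficient"):
            classify_symmetry(5, 5)

    def test_labels_cover_three_way_scheme(self):
        labels = {classify_symmetry(u, d)["label"]
                  for u, d in [(80, 20), (65, 35), (52, 48)]}
        assert labels == {"strong asymmetry", "weak asymmetry", "symmetric"}


class TestAngularCorrection:
    def vm_dataset(self, mu, n=50, kappa=20.0, seed=0):
        rng = np.random.default_rng(seed)
        angles = synth.VonMisesDirection(mu, kappa).sample(n, rng)
        return make_dataset(angles)

    def test_cell_already_at_90_gets_zero_delta(self):
        ds = make_dataset(np.full(10, 90.0))
        out, log = angular_correction(ds)
        assert log.iloc[0].delta_deg == 0.0
        np.testing.assert_array_equal(out.events.angle_deg, 90.0)

    def test_mu_30_rotated_plus_60(self):
        out, log = angular_correction(make_dataset(np.full(10, 30.0)))
        assert log.iloc[0].delta_deg == pytest.approx(60.0)
        mu, _ = circular_mean(out.events.angle_deg)
        assert mu == pytest.approx(90.0, abs=1e-9)

    def test_mu_200_targets_270_with_plus_70(self):
        out, log = angular_correction(make_dataset(np.full(10, 200.0)))
        assert log.iloc[0].delta_deg == pytest.approx(70.0)
        mu, _ = circular_mean(out.events.angle_deg)
        assert mu == pytest.approx(270.0, abs=1e-9)

    def test_rotation_bound_and_dispersion_preserved(self):
        rng = np.random.default_rng(3)
        for mu in rng.uniform(0, 360, 25):
            ds = self.vm_dataset(mu, seed=int(mu * 100) % 2**31)
            before = circular_variance(ds.events.angle_deg)
            out, log = angular_correction(ds)
            after = circular_variance(out.events.angle_deg)
            assert abs(before - after) < 1e-12
            assert abs(log.iloc[0].delta_deg) <= 90.0

    def test_too_few_events_left_uncorrected(self):
        out, log = angular_correction(make_dataset([30.0, 40.0]))
        assert not log.iloc[0].corrected
        assert log.iloc[0].flag == "too_few_events"
        np.testing.assert_array_equal(out.events.angle_deg, [30.0, 40.0])

    def test_uniform_cell_flagged_zero_resultant(self):
        angles = np.arange(0.0, 360.0, 45.0)  # perfectly balanced
        out, log = angular_correction(make_dataset(angles))
        assert log.iloc[0].flag == "zero_resultant"
        np.testing.assert_array_equal(out.events.angle_deg, angles)


class TestCompareGroups:
    def test_identical_groups_t_zero(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_hand_computed_two_sample_oracle(self):
        # a = 1..5, b = 2,4,..,10: pooled sp² = (4·2.5 + 4·10)/8 = 6.25,
        # t = (3 − 6) / (2.5·sqrt(2/5)) = −1.8974
        res = compare_groups([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res["t"] == pytest.approx(-3 / (2.5 * np.sqrt(0.4)), rel=1e-12)
        assert res["p"] == pytest.approx(0.0944, abs=5e-4)  # t-table, df = 8
        assert res["sem_a"] == pytest.approx(np.sqrt(2.5 / 5))

    def test_degenerate_zero_variance_equal_means(self):
        res = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert res["p"] == 1.0 and "degenerate" in res["flag"]

    @pytest.mark.parametrize("p,stars", [
        (0.0005, "***"), (0.005, "**"), (0.04, "*"), (0.2, "ns")])
    def test_significance_star_convention(self, p, stars):
        assert significance_stars(p) == stars
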