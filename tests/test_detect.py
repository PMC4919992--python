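"""Shift detection: reconstruction, difference profiles, centre of mass,
labelled calls and the whole-community qPCR check."""

import numpy as np
import pandas as pd
import pytest

from sipshift import (
    DetectionParams,
    bd_center_of_mass,
    detect_labelled,
    difference_profile,
    one_arm_taxa,
    reconstruct_total_community,
    total_shift_check,
)
from conftest import toy_run


DENS4 = [1.74, 1.72, 1.70, 1.68]


class TestReconstructTotalCommunity:
    def test_identical_profiles_pass_through(self):
        prof = np.array([0.2, 0.3, 0.5])
        run = toy_run(np.tile(prof[:, None], 4), DENS4, copies=[5, 1, 9, 2])
        for w in ("copies", "uniform"):
            np.testing.assert_allclose(
                reconstruct_total_community(run, w).to_numpy(), prof
            )

    def test_copy_weighted_mean_oracle(self):
        run = toy_run([[1.0, 0.0], [0.0, 1.0]], [1.72, 1.70], copies=[3, 1])
        out = reconstruct_total_community(run, "copies")
        np.testing.assert_allclose(out.to_numpy(), [0.75, 0.25])

    def test_uniform_equals_copies_when_copies_equal(self):
        run = toy_run(
            [[0.9, 0.1, 0.4], [0.1, 0.9, 0.6]], [1.73, 1.71, 1.69],
            copies=[7, 7, 7],
        )
        np.testing.assert_allclose(
            reconstruct_total_community(run, "uniform").to_numpy(),
            reconstruct_total_community(run, "copies").to_numpy(),
        )

    def test_all_zero_copies_rejected(self):
        run = toy_run([[1.0, 1.0]], [1.72, 1.70], copies=[0, 0])
        with pytest.raises(ValueError, match="zero"):
            reconstruct_total_community(run, "copies")


class TestDifferenceProfile:
    def test_identical_sets_give_zero(self, paired_runs):
        runs13, _, _ = paired_runs
        delta = difference_profile(runs13, runs13)
        assert np.abs(delta.to_numpy()).max() == 0.0

    def test_subtraction_oracle(self):
        r13 = toy_run([[0.1, 0.3], [0.9, 0.7]], [1.72, 1.70], treatment="13C")
        r12 = toy_run([[0.3, 0.1], [0.7, 0.9]], [1.72, 1.70])
        delta = difference_profile([r13], [r12], taxon="t0")
        np.testing.assert_allclose(delta.to_numpy(), [-0.2, 0.2])

    def test_equals_per_replicate_mean_of_differences(self, paired_runs):
        """With equal replicate counts, mean-of-arms equals averaging the
        per-replicate pairwise differences (brute-force oracle)."""
        runs13, runs12, _ = paired_runs
        delta = difference_profile(runs13, runs12)
        brute = sum(
            r13.normalized().abundance.to_numpy()
            - r12.normalized().abundance.to_numpy()
            for r13, r12 in zip(runs13, runs12)
        ) / len(runs13)
        np.testing.assert_allclose(delta.to_numpy(), brute, atol=1e-12)

    def test_antisymmetric_under_arm_swap(self, paired_runs):
        runs13, runs12, _ = paired_runs
        a = difference_profile(runs13, runs12).to_numpy()
        b = difference_profile(runs12, runs13).to_numpy()
        np.testing.assert_allclose(a, -b, atol=1e-15)

    def test_mismatched_fraction_counts_rejected(self):
        r13 = toy_run([[1.0, 1.0]], [1.72, 1.70], treatment="13C",
                      values_kind="counts")
        r12 = toy_run([[1.0, 1.0, 1.0]], [1.72, 1.70, 1.68],
                      values_kind="counts")
        with pytest.raises(ValueError, match="mismatch|differ"):
            difference_profile([r13], [r12])


class TestBdCenterOfMass:
    def test_single_fraction_gives_its_density(self):
        run = toy_run([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0]],
                      [1.74, 1.72, 1.70], copies=[1, 1, 1])
        assert bd_center_of_mass(run, "t0") == pytest.approx(1.72)

    def test_midpoint_oracle(self):
        run = toy_run([[0.5, 0.0, 0.5], [0.5, 1.0, 0.5]],
                      [1.74, 1.72, 1.70], copies=[1, 1, 1])
        assert bd_center_of_mass(run, "t0") == pytest.approx(1.72)

    def test_symmetric_band_centres(self):
        run = toy_run(
            [[0.2, 0.6, 0.2], [0.8, 0.4, 0.8]],
            [1.74, 1.72, 1.70], copies=[1, 1, 1],
        )
        assert bd_center_of_mass(run, "t0", "relative") == pytest.approx(1.72)

    def test_absent_taxon_flagged_nan(self):
        run = toy_run([[0.0, 0.0], [1.0, 1.0]], [1.72, 1.70], copies=[1, 1])
        assert np.isnan(bd_center_of_mass(run, "t0"))
        assert np.isnan(bd_center_of_mass(run, "nonexistent"))


class TestDetectLabelled:
    def test_null_identity_gives_no_calls(self, paired_runs):
        _, runs12, _ = paired_runs
        results = detect_labelled(runs12, runs12)
        assert not any(r.labelled for r in results)

    def test_known_guild_recovered(self, paired_runs):
        runs13, runs12, truth = paired_runs
        called = {r.taxon_id for r in detect_labelled(runs13, runs12) if r.labelled}
        assert called == truth

    def test_degenerate_thresholds_flag_every_positive_shift(self, paired_runs):
        runs13, runs12, _ = paired_runs
        params = DetectionParams(com_threshold=0.0, heavy_k=0, min_abund=0.0)
        results = detect_labelled(runs13, runs12, params)
        for r in results:
            if r.evaluable and r.com_shift > 0:
                assert r.labelled

    def test_invariant_to_row_and_replicate_order(self, paired_runs):
        runs13, runs12, _ = paired_runs
        base = {r.taxon_id: r.labelled for r in detect_labelled(runs13, runs12)}
        shuffled13 = [
            type(r)(**{**r.__dict__, "abundance": r.abundance.iloc[::-1]})
            for r in reversed(runs13)
        ]
        perm = {
            r.taxon_id: r.labelled
            for r in detect_labelled(shuffled13, list(reversed(runs12)))
        }
        assert base == perm

    def test_empty_arm_rejected(self, paired_runs):
        runs13, _, _ = paired_runs
        with pytest.raises(ValueError, match="replicate"):
            detect_labelled(runs13, [])

    def test_permutation_skipped_with_single_replicates(self, paired_runs):
        runs13, runs12, _ = paired_runs
        params = DetectionParams(n_perm=20, seed=0)
        with pytest.warns(UserWarning, match="permutation"):
            results = detect_labelled(runs13[:1], runs12[:1], params)
        assert all(r.p_value is None for r in results)

    def test_permutation_pvalues_support_true_calls(self, paired_runs):
        """With 3 vs 3 replicate gradients only 20 distinct arm
        partitions exist, so a decisive taxon's p floors near 1/20."""
        runs13, runs12, truth = paired_runs
        params = DetectionParams(n_perm=199, alpha=0.1, seed=5)
        results = detect_labelled(runs13, runs12, params)
        called = {r.taxon_id for r in results if r.labelled}
        assert called == truth
        by_id = {r.taxon_id: r for r in results}
        assert all(by_id[t].p_value <= 0.1 for t in truth)

    def test_one_arm_taxa_reported_separately(self, paired_runs):
        runs13, runs12, _ = paired_runs
        extra = runs13[0].abundance.copy()
        extra.loc["GHOST"] = 0
        extra.loc["GHOST", 1] = 5
        ghost_run = type(runs13[0])(
            **{**runs13[0].__dict__, "abundance": extra}
        )
        split = one_arm_taxa([ghost_run] + runs13[1:], runs12)
        assert split["only_13C"] == ["GHOST"]
        results = detect_labelled([ghost_run] + runs13[1:], runs12)
        assert "GHOST" not in {r.taxon_id for r in results}


class TestTotalShiftCheck:
    def test_identical_copy_curves(self):
        r13 = toy_run([[1.0] * 4], DENS4, treatment="13C",
                      copies=[1, 5, 3, 1], values_kind="counts")
        r12 = toy_run([[1.0] * 4], DENS4, copies=[1, 5, 3, 1],
                      values_kind="counts")
        res = total_shift_check([r13], [r12])
        assert res.shift == pytest.approx(0.0, abs=1e-15)
        assert not res.detected

    def test_one_fraction_discrete_shift_oracle(self):
        """Copies moved one fraction heavier shift the pool mean by one
        fraction width."""
        copies12 = np.array([0.0, 2.0, 6.0, 2.0])
        copies13 = np.array([2.0, 6.0, 2.0, 0.0])
        r13 = toy_run([[1.0] * 4], DENS4, treatment="13C", copies=copies13,
                      values_kind="counts")
        r12 = toy_run([[1.0] * 4], DENS4, copies=copies12, values_kind="counts")
        res = total_shift_check([r13], [r12])
        assert res.shift == pytest.approx(0.02, abs=1e-12)
        assert res.detected

    def test_missing_copies_rejected(self):
        r13 = toy_run([[1.0] * 4], DENS4, treatment="13C", values_kind="counts")
        r12 = toy_run([[1.0] * 4], DENS4, copies=[1, 1, 1, 1],
                      values_kind="counts")
        with pytest.raises(ValueError, match="copies"):
            total_shift_check([r13], [r12])

    def test_label_strength_flips_detection(self, rng):
        """Weakly labelled communities stay below the tolerance; fully
        labelled ones exceed it (generator ground truth)."""
        from sipshift import GradientConfig, Taxon, ATOM13C_NATURAL
        from sipshift.evaluate import paired_experiment
        from sipshift import make_community

        cfg = GradientConfig(seed=21)
        weak = make_community(50, 5, rng=np.random.default_rng(8),
                              labelled_atom13c=0.10)
        strong = [
            Taxon(t.taxon_id, t.gc,
                  0.99 if t.atom13c > ATOM13C_NATURAL else t.atom13c,
                  t.base_abundance)
            for t in weak
        ]
        w13, w12 = paired_experiment(weak, cfg, 3)
        s13, s12 = paired_experiment(strong, cfg, 3)
        assert not total_shift_check(w13, w12).detected
        assert total_shift_check(s13, s12).detected
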