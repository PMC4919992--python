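"""Gradient simulator: banding physics, fractionation, noise models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import erf

from sipshift import (
    ATOM13C_NATURAL,
    ExperimentDesign,
    GradientConfig,
    Taxon,
    fractionate,
    insilico_trflp,
    make_community,
    simulate_experiment,
    simulate_gradient,
    taxon_buoyant_density,
)
from sipshift.simulate import fraction_densities, fraction_edges


class TestBuoyantDensity:
    @pytest.mark.parametrize(
        "gc, atom13c, expected",
        [
            (0.0, ATOM13C_NATURAL, 1.660),      # intercept
            (0.5, ATOM13C_NATURAL, 1.7090),     # 1.660 + 0.098 * 0.5
            (0.5, 1.0, 1.7450),                 # full label adds the 0.036 shift
        ],
    )
    def test_examples(self, gc, atom13c, expected):
        assert taxon_buoyant_density(gc, atom13c) == pytest.approx(expected, abs=1e-9)

    @given(
        gc=st.floats(0.0, 1.0),
        x1=st.floats(0.0, 0.99),
        dx=st.floats(1e-6, 0.01),
    )
    def test_labelling_strictly_increases_density(self, gc, x1, dx):
        assert taxon_buoyant_density(gc, x1 + dx) > taxon_buoyant_density(gc, x1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            taxon_buoyant_density(1.2)
        with pytest.raises(ValueError):
            taxon_buoyant_density(0.5, -0.1)


class TestFractionate:
    def test_mass_conservation(self, rng):
        cfg = GradientConfig()
        taxa = make_community(40, 5, rng=rng)
        mass, tails = fractionate(taxa, cfg)
        total = mass.sum(axis=1) + tails.sum(axis=1)
        base = np.array([t.base_abundance for t in taxa])
        assert np.allclose(total, base, atol=1e-9)

    def test_sharp_band_lands_in_one_fraction(self):
        """Gaussian-integral oracle: a band centred at a fraction midpoint
        with sigma = width/8 keeps >=99.7% of its mass in that fraction."""
        cfg = GradientConfig(band_sigma=(1.775 - 1.665) / 12 / 8, smear=0.0)
        mid = fraction_densities(cfg)[5]
        gc = (mid - 1.660) / 0.098
        taxa = [Taxon("A", gc=gc, base_abundance=1.0)]
        mass, _ = fractionate(taxa, cfg)
        width = (cfg.density_max - cfg.density_min) / cfg.n_fractions
        oracle = erf(width / 2 / (np.sqrt(2) * cfg.band_sigma))
        assert oracle > 0.997
        assert mass.loc["A", 6] == pytest.approx(oracle, abs=1e-12)

    def test_mirror_symmetry(self):
        """Two taxa mirrored about the gradient centre give a mirrored
        mass matrix."""
        cfg = GradientConfig(smear=0.0)
        centre = (cfg.density_min + cfg.density_max) / 2
        d = 0.02
        gc_lo = (centre - d - 1.660) / 0.098
        gc_hi = (centre + d - 1.660) / 0.098
        taxa = [
            Taxon("lo", gc=gc_lo, base_abundance=0.5),
            Taxon("hi", gc=gc_hi, base_abundance=0.5),
        ]
        mass, _ = fractionate(taxa, cfg)
        np.testing.assert_allclose(
            mass.loc["lo"].to_numpy(), mass.loc["hi"].to_numpy()[::-1], atol=1e-12
        )

    def test_fraction_one_is_heaviest(self):
        cfg = GradientConfig()
        dens = fraction_densities(cfg)
        assert np.all(np.diff(dens) < 0)
        assert fraction_edges(cfg)[0] == cfg.density_max

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fractionate([], GradientConfig())

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError, match="band_sigma"):
            GradientConfig(band_sigma=0.0)

    def test_weighted_mean_density_converges_to_band_centre(self):
        """At fine fractionation with no smear, the mass-weighted mean
        density of a taxon approaches its configured band centre."""
        cfg = GradientConfig(n_fractions=120, smear=0.0)
        taxon = Taxon("A", gc=0.5, atom13c=1.0, base_abundance=1.0)
        mass, _ = fractionate([taxon], cfg)
        dens = fraction_densities(cfg)
        com = float(mass.loc["A"] @ dens / mass.loc["A"].sum())
        assert com == pytest.approx(taxon_buoyant_density(0.5, 1.0), abs=1e-3)


class TestSimulateGradient:
    def test_determinism(self, community, small_cfg):
        a = simulate_gradient(community, small_cfg, "13C")
        b = simulate_gradient(community, small_cfg, "13C")
        pd.testing.assert_frame_equal(a.abundance, b.abundance)
        np.testing.assert_array_equal(a.copies, b.copies)

    def test_12c_arm_ignores_labelling(self, community, small_cfg):
        """Under the unlabelled treatment the label designation is moot."""
        unlabelled = [
            Taxon(t.taxon_id, t.gc, ATOM13C_NATURAL, t.base_abundance)
            for t in community
        ]
        a = simulate_gradient(community, small_cfg, "12C")
        b = simulate_gradient(unlabelled, small_cfg, "12C")
        pd.testing.assert_frame_equal(a.abundance, b.abundance)

    def test_noise_free_limit_matches_mass_proportions(self, community):
        """With no overdispersion and huge depth, read proportions
        approach the per-fraction mass proportions."""
        cfg = GradientConfig(
            seq_depth=2_000_000, qpcr_cv=0.0, overdispersion=None, seed=5
        )
        run = simulate_gradient(community, cfg, "12C")
        mass, _ = fractionate(
            [Taxon(t.taxon_id, t.gc, ATOM13C_NATURAL, t.base_abundance)
             for t in community],
            cfg,
        )
        props = run.abundance.to_numpy() / cfg.seq_depth
        expected = mass.to_numpy() / mass.to_numpy().sum(axis=0)
        assert np.abs(props - expected).max() < 2e-3

    def test_full_label_shifts_copy_weighted_mean_density(self, community):
        """Simulation oracle at fine fractionation: the copy-weighted mean
        density of a fully labelled taxon sits ~(1 - smear) * 0.036 g/ml
        above its unlabelled position."""
        cfg = GradientConfig(n_fractions=120, qpcr_cv=0.0, seed=11)
        lab = [t for t in community if t.labelled][0]
        dens = fraction_densities(cfg)

        def com(run, taxon_id):
            # reads are depth-normalized per fraction; scale by the
            # fraction's copy total to recover the taxon's DNA mass
            m = run.abundance.loc[taxon_id].to_numpy() * run.copies
            return m @ dens / m.sum()

        r13 = simulate_gradient(community, cfg, "13C")
        r12 = simulate_gradient(community, cfg, "12C")
        shift = com(r13, lab.taxon_id) - com(r12, lab.taxon_id)
        expected = (1 - cfg.smear) * cfg.bd_label_shift * (
            (lab.atom13c - ATOM13C_NATURAL) / (1 - ATOM13C_NATURAL)
        )
        assert shift == pytest.approx(expected, abs=0.004)

    def test_dirichlet_multinomial_preserves_expected_proportions(self):
        """Over >=1000 draws the mean sampled proportion matches the mass
        proportion within 3 standard errors."""
        taxa = [
            Taxon("a", 0.45, base_abundance=0.6),
            Taxon("b", 0.50, base_abundance=0.3),
            Taxon("c", 0.55, base_abundance=0.1),
        ]
        cfg = GradientConfig(n_fractions=4, density_min=1.69, density_max=1.73,
                             band_sigma=0.02, seq_depth=500, seed=3)
        mass, _ = fractionate(taxa, cfg)
        expected = mass.to_numpy() / mass.to_numpy().sum(axis=0)
        rng = np.random.default_rng(17)
        draws = np.zeros((1000,) + expected.shape)
        for i in range(1000):
            run = simulate_gradient(taxa, cfg, "12C", rng=rng)
            draws[i] = run.abundance.to_numpy() / cfg.seq_depth
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(1000)
        assert np.all(np.abs(mean - expected) <= 3 * se + 1e-4)

    def test_empty_community_rejected(self, small_cfg):
        with pytest.raises(ValueError, match="empty"):
            simulate_gradient([], small_cfg, "12C")


class TestInsilicoTrflp:
    def test_injective_map_is_relabelling(self):
        mat = pd.DataFrame([[0.3, 0.1], [0.7, 0.9]], index=["x", "y"])
        out = insilico_trflp(mat, {"x": 100, "y": 205})
        assert list(out.index) == [100, 205]
        np.testing.assert_allclose(out.to_numpy(), mat.to_numpy())

    def test_shared_fragment_sums(self):
        mat = pd.DataFrame([[0.3], [0.2], [0.5]], index=["x", "y", "z"])
        out = insilico_trflp(mat, {"x": 56, "y": 56, "z": 148})
        assert out.loc[56, 0] == pytest.approx(0.5)
        assert out.loc[148, 0] == pytest.approx(0.5)

    def test_empty_column_preserved(self):
        mat = pd.DataFrame([[0.3, 0.0], [0.7, 0.0]], index=["x", "y"])
        out = insilico_trflp(mat, {"x": 56, "y": 148})
        assert out[1].sum() == 0.0

    def test_unmapped_taxon_named(self):
        mat = pd.DataFrame([[1.0]], index=["x"])
        with pytest.raises(ValueError, match="x"):
            insilico_trflp(mat, {})

    def test_length_range_enforced(self):
        mat = pd.DataFrame([[1.0]], index=["x"])
        with pytest.raises(ValueError, match="50"):
            insilico_trflp(mat, {"x": 30})


class TestSimulateExperiment:
    def test_design_bookkeeping(self, small_cfg, rng):
        taxa = {s: make_community(10, 2, rng=rng) for s in "DFW"}
        runs = simulate_experiment(taxa, small_cfg, ExperimentDesign(replicates=3))
        assert len(runs) == 18  # 3 soils x 2 treatments x 3 replicates
        assert all(r.n_fractions == 12 for r in runs)
        ids = {r.run_id for r in runs}
        assert len(ids) == 18

    def test_byte_identical_outputs_from_master_seed(self, small_cfg, tmp_path):
        from sipshift import write_fraction_tables

        rng1, rng2 = np.random.default_rng(4), np.random.default_rng(4)
        taxa1 = {"D": make_community(8, 1, rng=rng1)}
        taxa2 = {"D": make_community(8, 1, rng=rng2)}
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fraction_tables(
            simulate_experiment(taxa1, small_cfg, ExperimentDesign(soils=("D",))), d1
        )
        write_fraction_tables(
            simulate_experiment(taxa2, small_cfg, ExperimentDesign(soils=("D",))), d2
        )
        for name in ("runs.tsv", "fractions.tsv", "abundance.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_missing_soil_community_rejected(self, small_cfg, rng):
        with pytest.raises(ValueError, match="W"):
            simulate_experiment(
                {"D": make_community(5, 0, rng=rng)},
                small_cfg,
                ExperimentDesign(soils=("D", "W")),
            )


def test_make_community_sums_to_one(rng):
    taxa = make_community(50, 5, rng=rng)
    assert sum(t.base_abundance for t in taxa) == pytest.approx(1.0, abs=1e-9)
    labelled = [t for t in taxa if t.labelled]
    assert len(labelled) == 5
    assert all(t.base_abundance >= 0.01 for t in labelled)
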