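"""Synthetic-data generators: determinism, planted structure, truth bookkeeping."""

import numpy as np
import pytest

from cytodelim.extraction import extract_at_points
from cytodelim.morphometrics import wilcoxon_rank_sum
from cytodelim.overlap import kde_grid, schoeners_d, shared_grid_extent
from cytodelim.simulate import (
    ConfigurationError,
    NicheSimConfig,
    PositionStats,
    TraitGroupConfig,
    VariantSimConfig,
    gen_occurrences,
    gen_trait_table,
    gen_variants,
)
from cytodelim.thinning import haversine_km, thin
from cytodelim.variants import FilterConfig, run_cascade, singleton_filter


class TestOccurrenceGenerator:
    def test_seeded_determinism(self):
        a = gen_occurrences(NicheSimConfig(seed=11))
        b = gen_occurrences(NicheSimConfig(seed=11))
        assert a[0].to_frame().equals(b[0].to_frame())
        for la, lb in zip(a[1], b[1]):
            assert np.array_equal(la.values, lb.values)

    def test_different_seeds_differ(self):
        a = gen_occurrences(NicheSimConfig(seed=1))[0]
        b = gen_occurrences(NicheSimConfig(seed=2))[0]
        assert not a.to_frame().equals(b.to_frame())

    def test_raster_correlation_matches_target_exactly(self):
        cfg = NicheSimConfig(seed=4)
        _, layers, truth = gen_occurrences(cfg)
        vals = np.stack([l.values.ravel() for l in layers])
        assert np.allclose(np.corrcoef(vals), truth.layer_corr, atol=1e-9)

    def test_duplicate_fraction_plants_close_pairs(self):
        cfg = NicheSimConfig(seed=8, duplicate_fraction=0.2)
        occ, _, truth = gen_occurrences(cfg)
        n_dup = sum(truth.n_duplicates.values())
        assert n_dup == sum(
            round(0.2 * n) for n in cfg.n_records.values()
        )
        dup_records = [r for r in occ.records if r.source == "duplicate"]
        assert len(dup_records) == n_dup
        # thinning at 1 km must remove at least every planted duplicate
        thinned, rep = thin(occ, 1.0)
        assert len(rep.dropped) >= n_dup

    def test_zero_duplicate_fraction_plants_none(self):
        occ, _, truth = gen_occurrences(NicheSimConfig(seed=8, duplicate_fraction=0.0))
        assert sum(truth.n_duplicates.values()) == 0
        assert all(r.source != "duplicate" for r in occ.records)

    def test_environmental_covariance_converges(self):
        """Empirical covariance of extracted values approaches the configured
        covariance (10% of total scale at n=2000, fine spatial grid)."""
        target_cov = np.array([[0.16, 0.04], [0.04, 0.09]])
        cfg = NicheSimConfig(
            species_means={"a": np.array([0.3, -0.2]), "b": np.array([-0.5, 0.4])},
            species_covs={"a": target_cov, "b": target_cov},
            n_records={"a": 2000, "b": 2000},
            extent=(100.0, 20.0, 110.0, 30.0),
            cell_size=0.05,
            n_layers=2,
            layer_corr=np.array([[1.0, 0.2], [0.2, 1.0]]),
            duplicate_fraction=0.0,
            seed=21,
        )
        occ, layers, truth = gen_occurrences(cfg)
        env = extract_at_points(layers, occ)
        scale = np.sqrt(np.outer(np.diag(target_cov), np.diag(target_cov)))
        for sp in ("a", "b"):
            emp = np.cov(env.data[env.species == sp].to_numpy(), rowvar=False)
            assert np.all(np.abs(emp - target_cov) / scale < 0.10)
            mean = env.data[env.species == sp].mean().to_numpy()
            assert np.all(np.abs(mean - truth.species_means[sp]) < 0.05)

    def test_identical_niches_give_high_overlap(self):
        """Two species drawn from the same environmental Gaussian should have
        Schoener's D near 1 (bound from repeat simulation at n=500)."""
        cov = np.array([[0.09, 0.0], [0.0, 0.09]])
        cfg = NicheSimConfig(
            species_means={"a": np.zeros(2), "b": np.zeros(2)},
            species_covs={"a": cov, "b": cov},
            n_records={"a": 500, "b": 500},
            extent=(100.0, 20.0, 110.0, 30.0),
            cell_size=0.05,
            n_layers=2,
            layer_corr=np.eye(2),
            duplicate_fraction=0.0,
            seed=13,
        )
        occ, layers, _ = gen_occurrences(cfg)
        env = extract_at_points(layers, occ)
        pts = {sp: env.data[env.species == sp].to_numpy() for sp in ("a", "b")}
        pooled = np.vstack(list(pts.values()))
        extent = shared_grid_extent(pooled)
        d = schoeners_d(
            kde_grid(pts["a"], extent), kde_grid(pts["b"], extent)
        )
        assert d > 0.85

    def test_non_positive_definite_covariance_rejected(self):
        with pytest.raises(ConfigurationError, match="positive-definite"):
            NicheSimConfig(
                species_means={"a": np.zeros(2)},
                species_covs={"a": np.array([[1.0, 2.0], [2.0, 1.0]])},
                n_records={"a": 10},
                n_layers=2,
            )

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            NicheSimConfig(n_records={"C. paliurus": 0, "C. serrata": 5})


class TestTraitGenerator:
    def test_seeded_determinism(self):
        assert gen_trait_table(seed=3).equals(gen_trait_table(seed=3))

    def test_zero_sd_collapses_to_mean(self):
        cfg = {
            "sp": TraitGroupConfig(
                positions={"lateral": PositionStats(10, 8.0, 0.0, 4.0, 0.0)},
                pair_probs={4: 1.0},
                flower_diameter_mean=5.0,
                flower_diameter_sd=0.0,
            )
        }
        t = gen_trait_table(cfg, seed=0)
        assert np.all(t["length_cm"] == 8.0)
        assert np.all(t["width_cm"] == 4.0)
        assert np.all(t["flower_diameter_mm"] == 5.0)
        assert np.all(t["ratio"] == 2.0)

    def test_group_means_near_configured_truth(self):
        t = gen_trait_table(seed=5)
        lat = t[(t.species == "C. paliurus") & (t.position == "lateral")]
        se = 1.8 / np.sqrt(len(lat))
        assert abs(lat["length_cm"].mean() - 10.9) < 3 * se

    def test_planted_separation_detected_by_rank_sum(self):
        """5-SD group separation at n=30/group is essentially always detected."""
        def cfg(mean):
            return TraitGroupConfig(
                positions={"lateral": PositionStats(30, mean, 1.0, 4.0, 0.5)},
                pair_probs={4: 1.0},
                flower_diameter_mean=5.0,
                flower_diameter_sd=0.3,
            )
        t = gen_trait_table({"a": cfg(10.0), "b": cfg(15.0)}, seed=7)
        res = wilcoxon_rank_sum(
            t[t.species == "a"]["length_cm"], t[t.species == "b"]["length_cm"]
        )
        assert res.p_value < 0.001

    def test_negative_count_rejected(self):
        with pytest.raises(ConfigurationError):
            PositionStats(-1, 1.0, 0.1, 1.0, 0.1)

    def test_negative_sd_rejected(self):
        with pytest.raises(ConfigurationError):
            PositionStats(5, 1.0, -0.1, 1.0, 0.1)


class TestVariantGenerator:
    def test_seeded_determinism(self):
        a = gen_variants(VariantSimConfig(n_sites=300, seed=9))
        b = gen_variants(VariantSimConfig(n_sites=300, seed=9))
        assert np.array_equal(a[0].genotypes, b[0].genotypes)
        assert np.array_equal(a[0].depths, b[0].depths)
        assert a[3] == b[3]

    def test_truth_counts_match_cascade(self):
        vm, cds, te, truth = gen_variants(VariantSimConfig(n_sites=800, seed=17))
        _, report = run_cascade(vm, FilterConfig(), cds, te)
        assert report.survivor_counts() == truth.counts()

    def test_all_singletons_removed_by_singleton_filter(self):
        vm, _, _, truth = gen_variants(
            VariantSimConfig(n_sites=200, singleton_fraction=1.0, seed=2)
        )
        out, _ = singleton_filter(vm)
        assert out.n_sites == 0
        assert truth.n_singleton_sites == 200

    def test_constant_depth_disables_depth_filter(self):
        vm, cds, te, truth = gen_variants(
            VariantSimConfig(n_sites=300, depth_dispersion=None, seed=2)
        )
        assert truth.after_depth == truth.n_input
        from cytodelim.variants import depth_filter

        out, _ = depth_filter(vm)
        assert out.n_sites == vm.n_sites

    def test_positions_unique_and_in_range(self):
        vm, _, _, _ = gen_variants(VariantSimConfig(n_sites=500, seed=4))
        for c in set(vm.chrom.astype(str)):
            p = vm.pos[vm.chrom.astype(str) == c]
            assert len(np.unique(p)) == len(p)
            assert p.min() >= 1

    def test_ploidy_structure(self):
        vm, _, _, _ = gen_variants(VariantSimConfig(n_sites=50, seed=4))
        from cytodelim.variants import UNUSED

        for s, ploidy in enumerate(vm.ploidies):
            used = vm.genotypes[:, s, :ploidy]
            assert np.all(used != UNUSED)
            assert np.all(vm.genotypes[:, s, ploidy:] == UNUSED)

    def test_too_many_sites_rejected(self):
        with pytest.raises(ConfigurationError):
            VariantSimConfig(chrom_lengths={"c": 100}, n_sites=200)
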