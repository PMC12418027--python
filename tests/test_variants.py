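"""Neutral-SNP filter cascade, ploidy-aware Dxy, STRUCTURE export, VCF I/O."""

import itertools

import numpy as np
import pytest

from conftest import build_matrix
from cytodelim.variants import (
    FilterConfig,
    IntervalError,
    depth_filter,
    dxy,
    merge_intervals,
    region_exclude,
    run_cascade,
    singleton_filter,
    spacing_thin,
    structure_rows,
)
from cytodelim.vcfio import read_bed, read_gff_cds, read_vcf, write_bed, write_vcf

DIPS = [("d1", 2), ("d2", 2)]
MIXED = [("d1", 2), ("t1", 4)]


def site(pos, gts, dp=None, chrom="CHR1"):
    d = {"pos": pos, "gts": gts, "chrom": chrom}
    if dp is not None:
        d["dp"] = dp
    return d


class TestDepthFilter:
    def test_equal_depths_all_retained(self):
        vm = build_matrix(DIPS, [site(p, [(0, 1), (0, 0)], dp=[15, 15]) for p in (1, 2, 3)])
        out, _ = depth_filter(vm)
        assert out.n_sites == 3

    def test_inclusive_boundaries(self):
        # site depths 10, 61, 30, 19: mean = 30 -> window [10, 60]
        depths = [[5, 5], [31, 30], [15, 15], [10, 9]]
        vm = build_matrix(DIPS, [site(i + 1, [(0, 1), (0, 0)], dp=d)
                                 for i, d in enumerate(depths)])
        assert vm.site_depths().mean() == 30.0
        out, _ = depth_filter(vm)
        assert out.pos.tolist() == [1, 3, 4]  # 61 > 2*30 removed; 10 == 30/3 kept

    def test_no_depths_error(self):
        vm = build_matrix(DIPS, [site(1, [(0, 1), (0, 0)], dp=[0, 0])])
        with pytest.raises(ValueError, match="depth"):
            depth_filter(vm)

    def test_per_sample_mode(self):
        # sample 2's depth at site 2 is > 2x its own mean
        depths = [[10, 10], [10, 50], [10, 12]]
        vm = build_matrix(DIPS, [site(i + 1, [(0, 1), (0, 0)], dp=d)
                                 for i, d in enumerate(depths)])
        out, _ = depth_filter(vm, mode="per_sample")
        assert out.pos.tolist() == [1, 3]


class TestRegionExclude:
    def test_cds_flank_boundary(self):
        vm = build_matrix(DIPS, [site(3001, [(0, 1), (0, 0)]),
                                 site(4001, [(0, 1), (0, 0)])])
        cds = {"CHR1": np.array([[1000, 2000]])}
        out, _ = region_exclude(vm, cds, {}, flank=2000)
        # union [0, 4000): 0-based 3000 removed, 4000 retained
        assert out.pos.tolist() == [4001]

    def test_te_exclusion_no_flank(self):
        vm = build_matrix(DIPS, [site(500, [(0, 1), (0, 0)]),
                                 site(1500, [(0, 1), (0, 0)])])
        te = {"CHR1": np.array([[400, 600]])}
        out, _ = region_exclude(vm, {}, te, flank=2000)
        assert out.pos.tolist() == [1500]  # TE intervals are not flanked

    def test_empty_intervals_remove_nothing(self):
        vm = build_matrix(DIPS, [site(p, [(0, 1), (0, 0)]) for p in (10, 20)])
        out, _ = region_exclude(vm, {}, {})
        assert out.n_sites == 2

    def test_overlapping_intervals_union(self):
        vm = build_matrix(DIPS, [site(p, [(0, 1), (0, 0)]) for p in (50, 150, 250)])
        te = {"CHR1": np.array([[0, 120], [100, 200], [110, 190]])}
        out, _ = region_exclude(vm, {}, te, flank=0)
        assert out.pos.tolist() == [250]

    def test_malformed_interval_rejected(self):
        vm = build_matrix(DIPS, [site(1, [(0, 1), (0, 0)])])
        with pytest.raises(IntervalError):
            region_exclude(vm, {"CHR1": np.array([[100, 100]])}, {})
        with pytest.raises(IntervalError):
            merge_intervals(np.array([[5, 2]]))


class TestSingletonFilter:
    def test_tetraploid_single_alt_copy_removed(self):
        vm = build_matrix(MIXED, [site(1, [(0, 0), (0, 0, 0, 1)])])
        out, _ = singleton_filter(vm)
        assert out.n_sites == 0

    def test_two_carriers_retained(self):
        vm = build_matrix(MIXED, [site(1, [(0, 1), (0, 0, 0, 1)])])
        out, _ = singleton_filter(vm)
        assert out.n_sites == 1

    def test_reference_singleton_removed(self):
        # alt nearly fixed: the single remaining ref copy is the minor allele
        vm = build_matrix(MIXED, [site(1, [(1, 1), (0, 1, 1, 1)])])
        out, _ = singleton_filter(vm)
        assert out.n_sites == 0

    def test_monomorphic_site_not_a_singleton(self):
        vm = build_matrix(MIXED, [site(1, [(0, 0), (0, 0, 0, 0)])])
        out, _ = singleton_filter(vm)
        assert out.n_sites == 1

    def test_missing_copies_not_counted(self):
        # only the tetraploid is called; one alt copy among its 4 -> singleton
        vm = build_matrix(MIXED, [site(1, [None, (0, 0, 0, 1)])])
        out, _ = singleton_filter(vm)
        assert out.n_sites == 0


class TestSpacingThin:
    def test_greedy_keeps_first_then_next_far_enough(self):
        vm = build_matrix(DIPS, [site(p, [(0, 1), (0, 0)])
                                 for p in (1000, 15000, 25000)])
        out, _ = spacing_thin(vm, 20000)
        assert out.pos.tolist() == [1000, 25000]

    def test_single_site_per_chromosome_kept(self):
        vm = build_matrix(DIPS, [site(5, [(0, 1), (0, 0)], chrom="CHR1"),
                                 site(7, [(0, 1), (0, 0)], chrom="CHR2")])
        out, _ = spacing_thin(vm, 20000)
        assert out.n_sites == 2

    def test_retained_pairs_respect_min_dist(self, rng):
        pos = np.sort(rng.choice(500_000, size=150, replace=False) + 1)
        vm = build_matrix(DIPS, [site(int(p), [(0, 1), (0, 0)]) for p in pos])
        out, _ = spacing_thin(vm, 20000)
        diffs = np.diff(out.pos)
        assert np.all(diffs >= 20000)

    def test_unsorted_input_warns_and_sorts(self):
        vm = build_matrix(DIPS, [site(30000, [(0, 1), (0, 0)]),
                                 site(1000, [(0, 1), (0, 0)])])
        with pytest.warns(UserWarning, match="sort"):
            out, _ = spacing_thin(vm, 20000)
        assert out.pos.tolist() == [1000, 30000]


class TestCascade:
    def test_report_counts_chain(self):
        vm = build_matrix(DIPS, [site(p, [(0, 1), (0, 0)], dp=[10, 10])
                                 for p in (1000, 15000, 25000)])
        out, report = run_cascade(vm, FilterConfig())
        stages = report.to_dict()["stages"]
        assert [s["stage"] for s in stages] == ["depth", "region", "singleton", "spacing"]
        for s in stages:
            assert s["n_input"] - s["n_removed"] == s["n_survivors"]
        assert stages[-1]["n_survivors"] == out.n_sites

    def test_singleton_toggle_monotone(self):
        vm = build_matrix(MIXED, [site(1, [(0, 0), (0, 0, 0, 1)], dp=[10, 10]),
                                  site(30000, [(0, 1), (0, 0, 1, 1)], dp=[10, 10])])
        with_f, _ = run_cascade(vm, FilterConfig())
        without_f, _ = run_cascade(vm, FilterConfig(remove_singletons=False))
        assert without_f.n_sites >= with_f.n_sites


class TestDxy:
    def test_identical_groups_zero(self):
        vm = build_matrix(DIPS + [("d3", 2), ("d4", 2)],
                          [site(1, [(0, 1), (0, 0), (0, 1), (0, 0)])])
        res = dxy(vm, {"g1": ["d1", "d2"], "g2": ["d3", "d4"]})
        # same allele-frequency in both groups is not zero divergence per copy
        # pair, but identical *fixed* groups are:
        vm2 = build_matrix(DIPS + [("d3", 2)], [site(1, [(0, 0), (0, 0), (0, 0)])])
        res2 = dxy(vm2, {"g1": ["d1", "d2"], "g2": ["d3"]})
        assert res2[("g1", "g2")] == 0.0

    def test_fixed_difference_fraction(self):
        sites = [site(i + 1, [(0, 0), (1, 1)]) for i in range(1)]
        sites += [site(i + 10, [(0, 0), (0, 0)]) for i in range(9)]
        vm = build_matrix(DIPS, sites)
        res = dxy(vm, {"g1": ["d1"], "g2": ["d2"]})
        assert res[("g1", "g2")] == pytest.approx(0.1)

    def test_diploid_tetraploid_copy_pair_enumeration(self):
        # copies (0,1) vs (0,0,0,1): 8 pairs, 4 differ -> 0.5
        vm = build_matrix(MIXED, [site(1, [(0, 1), (0, 0, 0, 1)])])
        res = dxy(vm, {"dip": ["d1"], "tet": ["t1"]})
        assert res[("dip", "tet")] == pytest.approx(0.5)

    def test_matches_brute_force_over_copy_pairs(self, rng):
        """Independent oracle: explicit loop over all inter-group copy pairs."""
        samples = [("a1", 2), ("a2", 4), ("b1", 2), ("b2", 4)]
        sites = []
        for p in range(1, 13):
            gts = []
            for _, ploidy in samples:
                if rng.random() < 0.15:
                    gts.append(None)
                else:
                    gts.append(tuple(int(a) for a in rng.integers(0, 2, ploidy)))
            sites.append(site(p, gts))
        vm = build_matrix(samples, sites)
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        res = dxy(vm, groups)

        idx = {name: i for i, (name, _) in enumerate(samples)}
        total = 0.0
        for s_ in sites:
            copies = {g: [] for g in groups}
            for g, members in groups.items():
                for m in members:
                    gt = s_["gts"][idx[m]]
                    if gt is not None:
                        copies[g].extend(gt)
            pairs = list(itertools.product(copies["A"], copies["B"]))
            if pairs:
                total += sum(1 for a, b in pairs if a != b) / len(pairs)
        assert res[("A", "B")] == pytest.approx(total / len(sites), abs=1e-12)

    def test_symmetric_in_group_order(self):
        vm = build_matrix(MIXED, [site(1, [(0, 1), (0, 0, 1, 1)])])
        r1 = dxy(vm, {"x": ["d1"], "y": ["t1"]})
        r2 = dxy(vm, {"y": ["t1"], "x": ["d1"]})
        assert r1[("x", "y")] == pytest.approx(r2[("y", "x")])

    def test_all_missing_group_rejected(self):
        vm = build_matrix(MIXED, [site(1, [None, (0, 0, 0, 1)])])
        with pytest.raises(ValueError, match="non-missing"):
            dxy(vm, {"x": ["d1"], "y": ["t1"]})


class TestStructure:
    def test_tetraploid_four_allele_rows(self):
        vm = build_matrix([("t1", 4)], [site(1, [(0, 0, 1, 1)])])
        rows = structure_rows(vm)
        assert [r[1] for r in rows] == [[0], [0], [1], [1]]

    def test_diploid_padded_with_missing_rows(self):
        vm = build_matrix([("d1", 2)], [site(1, [(0, 1)])])
        rows = structure_rows(vm)
        assert [r[1] for r in rows] == [[0], [1], [-9], [-9]]

    def test_row_count_is_four_per_individual(self):
        vm = build_matrix(MIXED + [("d9", 2)],
                          [site(1, [(0, 1), (0, 0, 1, 1), (1, 1)]),
                           site(2, [(0, 0), (0, 0, 0, 1), None])])
        rows = structure_rows(vm)
        assert len(rows) == 4 * 3
        # missing diploid genotype coded -9 in its two genotype rows
        d9_rows = [r[1] for r in rows if r[0] == "d9"]
        assert d9_rows[0][1] == -9 and d9_rows[1][1] == -9


class TestVcfIO:
    def test_roundtrip_mixed_ploidy(self, tmp_path, rng):
        samples = [("dip", 2), ("tet", 4)]
        sites = []
        for p in sorted(rng.choice(10_000, 20, replace=False) + 1):
            gts = []
            for _, ploidy in samples:
                if rng.random() < 0.1:
                    gts.append(None)
                else:
                    gts.append(tuple(int(a) for a in rng.integers(0, 2, ploidy)))
            sites.append(site(int(p), gts, dp=list(rng.integers(5, 60, 2))))
        vm = build_matrix(samples, sites)
        path = tmp_path / "mixed.vcf"
        write_vcf(vm, path)
        back = read_vcf(path)
        assert back.samples == vm.samples
        assert np.array_equal(back.ploidies, vm.ploidies)
        assert np.array_equal(back.genotypes, vm.genotypes)
        assert np.array_equal(back.depths, vm.depths)
        assert back.pos.tolist() == vm.pos.tolist()

    def test_tetraploid_gt_text(self, tmp_path):
        vm = build_matrix([("t1", 4)], [site(1, [(0, 0, 0, 1)])])
        path = tmp_path / "t.vcf"
        write_vcf(vm, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert "0/0/0/1" in body[0]

    def test_bed_roundtrip(self, tmp_path):
        iv = {"CHR1": np.array([[0, 100], [500, 900]]), "CHR2": np.array([[5, 10]])}
        p = tmp_path / "x.bed"
        write_bed(iv, p)
        back = read_bed(p)
        assert set(back) == {"CHR1", "CHR2"}
        assert np.array_equal(back["CHR1"], iv["CHR1"])

    def test_gff_cds_one_based_conversion(self, tmp_path):
        p = tmp_path / "x.gff3"
        p.write_text(
            "##gff-version 3\n"
            "CHR1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=g1\n"
            "CHR1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=c1\n"
        )
        out = read_gff_cds(p)
        assert out["CHR1"].tolist() == [[100, 200]]
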