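"""Array screens: deterministic segmentation, CNV prioritization, LCSH
detection, the exact Hardy-Weinberg test against an exhaustive-enumeration
oracle, and composite CNV+SNV logic."""

from fractions import Fraction
from math import comb, factorial

import numpy as np
import pytest
from intervaltree import IntervalTree

from mitodx.array_cnv import (
    CnvSegment,
    Probe,
    detect_composite_cnv_snv,
    detect_lcsh,
    hwe_exact_test,
    hwe_screen,
    prioritize_cnv,
    reciprocal_overlap,
    segment_copy_number,
)
from mitodx.core import MitodxError


def probes_from(log2_values, chrom="chr1", spacing=28_000, genotype="AB"):
    return [
        Probe(chrom, (i + 1) * spacing, genotype, v) for i, v in enumerate(log2_values)
    ]


class TestSegmentation:
    def test_sixty_probe_deletion_called_once(self):
        # 60 consecutive probes at log2 ~ -1.0 spanning ~1.68 Mb
        values = [0.0] * 20 + [-1.0] * 60 + [0.0] * 20
        segs = segment_copy_number(probes_from(values))
        assert len(segs) == 1
        seg = segs[0]
        assert seg.state == "deletion"
        assert seg.n_probes == 60
        assert seg.start == 21 * 28_000 and seg.end == 80 * 28_000
        # inclusive span: 59 probe spacings + 1 bp
        assert seg.size_kb == pytest.approx(1652.001)

    def test_flat_profile_no_segments(self):
        assert segment_copy_number(probes_from([0.0] * 100)) == []

    def test_probe_count_gate(self):
        values = [0.0] * 10 + [-1.0] * 2 + [0.0] * 10
        assert segment_copy_number(probes_from(values), min_probes=10) == []

    def test_gap_tolerance_merges_across_small_gaps(self):
        values = [-1.0] * 6 + [0.0] * 2 + [-1.0] * 6
        segs = segment_copy_number(probes_from(values), min_probes=10, max_gap=2)
        assert len(segs) == 1 and segs[0].n_probes == 12

    def test_gap_larger_than_tolerance_splits(self):
        values = [-1.0] * 6 + [0.0] * 3 + [-1.0] * 6
        assert segment_copy_number(probes_from(values), min_probes=10, max_gap=2) == []

    def test_duplications_called_separately(self):
        values = [0.0] * 12 + [0.4] * 15 + [0.0] * 12
        segs = segment_copy_number(probes_from(values))
        assert [s.state for s in segs] == ["duplication"]

    def test_unsorted_probes_raise(self):
        plist = probes_from([-1.0] * 12)
        plist[0], plist[5] = plist[5], plist[0]
        with pytest.raises(MitodxError):
            segment_copy_number(plist)

    def test_boundaries_deterministic(self):
        values = [0.0] * 5 + [-0.9] * 20 + [0.0] * 5
        a = segment_copy_number(probes_from(values))
        b = segment_copy_number(probes_from(values))
        assert a == b


def brute_force_reciprocal_overlap(a, b):
    """Oracle: count shared 1-based positions explicitly."""
    pa = set(range(a[0], a[1] + 1))
    pb = set(range(b[0], b[1] + 1))
    inter = len(pa & pb)
    if inter == 0:
        return 0.0
    return min(inter / len(pa), inter / len(pb))


class TestCnvPrioritization:
    def tree(self, *ivals):
        trees = {}
        for chrom, start, end, name in ivals:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
        return trees

    def test_large_deletion_passes_and_gets_disorder_annotation(self):
        seg = CnvSegment("chr6", 2_000_001, 3_675_000, "deletion", 80)
        kept = prioritize_cnv(
            [seg],
            control_cnvs={},
            disorder_regions=self.tree(("chr6", 1_900_000, 3_800_000, "CHD_region")),
        )
        assert len(kept) == 1
        assert kept[0].size_kb == pytest.approx(1675.0)
        assert kept[0].disorder_annotations == ["CHD_region"]

    def test_99kb_segment_fails_size_gate(self):
        seg = CnvSegment("chr2", 100_001, 199_000, "deletion", 12)
        assert seg.size_kb == pytest.approx(99.0)
        assert prioritize_cnv([seg], {}, {}) == []

    def test_control_overlap_drop_matches_brute_force(self):
        seg = CnvSegment("chr3", 1_000_001, 1_200_000, "deletion", 20)
        control = (1_010_001, 1_190_000)  # 90% reciprocal overlap
        frac = brute_force_reciprocal_overlap((seg.start, seg.end), control)
        assert frac == pytest.approx(
            reciprocal_overlap(seg.start, seg.end, *control)
        )
        assert frac >= 0.5
        trees = self.tree(("chr3", control[0] - 1, control[1], "ctrl"))
        assert prioritize_cnv([seg], trees, {}) == []

    def test_small_control_overlap_retained(self):
        seg = CnvSegment("chr3", 1_000_001, 1_200_000, "deletion", 20)
        trees = self.tree(("chr3", 1_180_000, 1_500_000, "ctrl"))
        assert len(prioritize_cnv([seg], trees, {})) == 1


class TestLcsh:
    def test_planted_stretch_recovered(self):
        spacing = 20_000
        probes = []
        rng = np.random.default_rng(5)
        for i in range(500):
            pos = (i + 1) * spacing
            inside = 2_000_000 <= pos <= 4_800_000  # 2.8 Mb window
            gt = ("AA" if rng.random() < 0.5 else "BB") if inside else (
                "AB" if rng.random() < 0.35 else ("AA" if rng.random() < 0.5 else "BB")
            )
            probes.append(Probe("chr2", pos, gt, 0.0))
        runs = detect_lcsh(probes, min_mb=1.0)
        big = [r for r in runs if r.length_mb > 2.0]
        assert len(big) == 1
        run = big[0]
        assert run.start <= 2_000_000 and run.end >= 4_800_000
        # the run covers the planted window; boundaries may extend a few
        # probes into the flanks wherever background genotypes happen to be
        # homozygous, so the recovered length is 2.8 Mb plus a small overhang
        assert 2.8 <= run.length_mb <= 2.8 + 12 * spacing / 1e6

    def test_alternating_genotypes_no_runs(self):
        probes = [
            Probe("chr1", (i + 1) * 10_000, "AA" if i % 2 else "AB", 0.0)
            for i in range(200)
        ]
        assert detect_lcsh(probes, min_mb=0.05) == []

    def test_short_stretch_threshold_dependent(self):
        # a 0.3 Mb homozygous stretch is invisible at 1.0 Mb but reported at 0.1 Mb
        probes = [
            Probe("chr1", (i + 1) * 10_000, "AB", 0.0) for i in range(20)
        ] + [
            Probe("chr1", 200_000 + (i + 1) * 10_000, "AA", 0.0) for i in range(30)
        ] + [
            Probe("chr1", 500_000 + (i + 1) * 10_000, "AB", 0.0) for i in range(20)
        ]
        assert detect_lcsh(probes, min_mb=1.0) == []
        runs = detect_lcsh(probes, min_mb=0.1)
        assert len(runs) == 1 and runs[0].length_mb == pytest.approx(0.29, abs=1e-3)

    def test_runs_nonoverlapping_and_maximal(self):
        rng = np.random.default_rng(17)
        probes = [
            Probe("chr4", (i + 1) * 10_000,
                  "AB" if rng.random() < 0.4 else "AA", 0.0)
            for i in range(2000)
        ]
        runs = detect_lcsh(probes, min_mb=0.05)
        by_pos = {p.pos: p for p in probes}
        for a, b in zip(runs, runs[1:]):
            assert a.end < b.start
        for r in runs:
            # extending either end would include a heterozygous probe
            left = [p for p in probes if p.pos < r.start]
            right = [p for p in probes if p.pos > r.end]
            if left:
                assert left[-1].genotype == "AB"
            if right:
                assert right[0].genotype == "AB"
            inside = [p for p in probes if r.start <= p.pos <= r.end]
            assert all(p.genotype in ("AA", "BB") for p in inside)


def oracle_hwe(n_AA, n_Aa, n_aa):
    """Exhaustive-enumeration exact test in rational arithmetic."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare, common = min(n_a, n_A), max(n_a, n_A)
    if rare == 0:
        return 1.0

    def ways(het):
        hom_rare = (rare - het) // 2
        hom_common = (common - het) // 2
        return (
            Fraction(factorial(n), factorial(het) * factorial(hom_rare) * factorial(hom_common))
            * 2 ** het
        )

    denom = Fraction(factorial(2 * n), factorial(n_a) * factorial(n_A))
    obs = ways(n_Aa) / denom
    total = Fraction(0)
    for het in range(rare % 2, rare + 1, 2):
        p = ways(het) / denom
        if p <= obs:
            total += p
    return float(total)


class TestHweExact:
    def test_founder_pattern_matches_oracle(self):
        # three rare homozygotes and a single carrier in a 142-patient cohort
        counts = (138, 1, 3)
        assert hwe_exact_test(*counts) == pytest.approx(oracle_hwe(*counts), rel=1e-9)
        assert hwe_exact_test(*counts) < 1e-4

    def test_exact_proportions_give_p_one(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_monomorphic_p_one(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    def test_negative_counts_raise(self):
        with pytest.raises(MitodxError):
            hwe_exact_test(-1, 2, 3)

    def test_matches_oracle_for_all_triples_up_to_n30(self):
        for n in range(1, 31):
            for n_AA in range(n + 1):
                for n_Aa in range(n - n_AA + 1):
                    n_aa = n - n_AA - n_Aa
                    got = hwe_exact_test(n_AA, n_Aa, n_aa)
                    want = oracle_hwe(n_AA, n_Aa, n_aa)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (
                        n_AA, n_Aa, n_aa,
                    )


class TestHweScreen:
    def test_founder_variant_flagged_among_background(self):
        counts = {
            "founder": (138, 1, 3),
            "bg1": (100, 40, 2),
            "bg2": (120, 20, 2),
        }
        results = {r.key: r for r in hwe_screen(counts)}
        assert results["founder"].violated
        assert not results["bg1"].violated

    def test_bonferroni_scales_with_screen_size(self):
        counts_small = {"v": (50, 2, 3)}
        p = hwe_exact_test(50, 2, 3)
        many = {f"v{i}": (55, 10, 0) for i in range(200)}
        many["v"] = (50, 2, 3)
        solo = hwe_screen(counts_small)[0]
        multi = {r.key: r for r in hwe_screen(many)}["v"]
        assert solo.p_value == pytest.approx(p)
        assert solo.violated and not multi.violated


class TestComposite:
    GENES = {"GX": ("chr17", 1_000_000, 1_050_000)}

    def seg(self):
        return CnvSegment("chr17", 900_000, 2_300_000, "deletion", 60)

    def test_het_deletion_plus_het_variant_is_biallelic_candidate(self):
        out = detect_composite_cnv_snv(
            [self.seg()], self.GENES, {"GX": [("chr17:1000100:G>A", "het")]}
        )
        assert len(out) == 1 and out[0].gene == "GX" and out[0].note == ""

    def test_deletion_without_variant_gives_no_composite(self):
        assert detect_composite_cnv_snv([self.seg()], self.GENES, {}) == []

    def test_hom_variant_under_het_deletion_flagged_hemizygous(self):
        out = detect_composite_cnv_snv(
            [self.seg()], self.GENES, {"GX": [("chr17:1000100:G>A", "hom_alt")]}
        )
        assert len(out) == 1 and "hemizygous" in out[0].note

    def test_duplication_not_composite(self):
        dup = CnvSegment("chr17", 900_000, 2_300_000, "duplication", 60)
        assert detect_composite_cnv_snv(
            [dup], self.GENES, {"GX": [("chr17:1000100:G>A", "het")]}
        ) == []
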