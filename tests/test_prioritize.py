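"""The exome filter cascade: per-filter semantics, recovery pass, and the
order-invariance / monotonicity properties."""

import numpy as np
import pytest

from mitodx.core import AnnotatedVariant, GeneSets, GenotypeCall, Gt, MitodxError, VariantKey
from mitodx.prioritize import (
    FILTER_ORDER,
    FilterConfig,
    evaluate_all,
    filter_case_recurrence,
    filter_deleteriousness,
    filter_functional_class,
    filter_population_frequency,
    filter_segdup,
    prioritize_patient,
)

CFG = FilterConfig()


def make_variant(i=1, gene="G0001", fclass="missense", maf=None, sift=0.01,
                 gerp=4.0, segdup=False, alleles=0, artifact=False,
                 medical_impact=False):
    return AnnotatedVariant(
        key=VariantKey("chr1", 1000 + i, "A", "G"),
        gene=gene,
        functional_class=fclass,
        maf=maf or {},
        sift=sift,
        gerp=gerp,
        in_segdup=segdup,
        case_allele_count=alleles,
        artifact_flag=artifact,
        dbsnp_medical_impact=medical_impact,
    )


class TestFunctionalClass:
    @pytest.mark.parametrize(
        "fclass,kept",
        [
            ("missense", True),
            ("nonsense", True),
            ("splice_site", True),
            ("frameshift_indel", True),  # coding indels are protein-altering
            ("inframe_indel", True),
            ("other", False),  # synonymous and the like
        ],
    )
    def test_protein_altering_classes_kept(self, fclass, kept):
        keep, _ = filter_functional_class(make_variant(fclass=fclass), CFG)
        assert keep is kept

    def test_unknown_class_raises_rather_than_keeps(self):
        v = make_variant()
        v.functional_class = "startloss"
        with pytest.raises(MitodxError):
            filter_functional_class(v, CFG)


class TestPopulationFrequency:
    def test_exac_above_threshold_removed_with_panel_named(self):
        keep, reason = filter_population_frequency(
            make_variant(maf={"exac": 0.002}), CFG
        )
        assert not keep and "exac" in reason

    def test_novel_variant_kept(self):
        keep, _ = filter_population_frequency(make_variant(maf={}), CFG)
        assert keep

    @pytest.mark.parametrize(
        "panel,freq,kept",
        [
            ("hgvd", 0.004, True),   # boundary: strictly-greater removal
            ("hgvd", 0.0041, False),
            ("dbsnp137", 0.010, True),
            ("dbsnp137", 0.011, False),
            ("1kg", 0.010, True),
            ("esp6500", 0.0011, False),
            ("1kjpn", 0.004, True),
        ],
    )
    def test_strict_inequality_boundaries(self, panel, freq, kept):
        keep, _ = filter_population_frequency(make_variant(maf={panel: freq}), CFG)
        assert keep is kept

    def test_dbsnp_medical_impact_exempt_from_dbsnp_filter(self):
        v = make_variant(maf={"dbsnp137": 0.05}, medical_impact=True)
        keep, _ = filter_population_frequency(v, CFG)
        assert keep

    def test_frequency_outside_unit_interval_raises(self):
        v = make_variant()
        v.maf["exac"] = 1.2  # bypasses the dataclass check deliberately
        with pytest.raises(MitodxError):
            filter_population_frequency(v, CFG)


class TestCaseRecurrence:
    @pytest.mark.parametrize(
        "alleles,kept",
        [
            (10, False),  # 5 homozygous cases
            (9, True),    # 9 het carriers: boundary
            (9, True),    # 4 hom + 1 het = 9 by the allele-sum rule
            (11, False),
        ],
    )
    def test_ten_allele_exclusion(self, alleles, kept):
        keep, _ = filter_case_recurrence(make_variant(alleles=alleles), CFG)
        assert keep is kept


class TestDeleteriousness:
    def test_tolerated_sift_removed(self):
        keep, reason = filter_deleteriousness(make_variant(sift=0.40), CFG)
        assert not keep and "SIFT" in reason

    def test_damaging_conserved_kept(self):
        keep, _ = filter_deleteriousness(make_variant(sift=0.01, gerp=4.1), CFG)
        assert keep

    def test_missing_sift_never_removes(self):
        # nonsense variants have no SIFT score but must survive
        keep, _ = filter_deleteriousness(
            make_variant(fclass="nonsense", sift=None, gerp=3.0), CFG
        )
        assert keep

    def test_unconserved_removed(self):
        keep, reason = filter_deleteriousness(make_variant(gerp=1.0), CFG)
        assert not keep and "GERP" in reason


def test_segdup_filter():
    assert not filter_segdup(make_variant(segdup=True), CFG)[0]
    assert filter_segdup(make_variant(segdup=False), CFG)[0]


# ---------------------------------------------------------------------------
# cascade-level behaviour
# ---------------------------------------------------------------------------

def _gene_sets(genes, mito=()):
    return GeneSets(set(), set(mito), set(genes))


def _run(variants, patient="P", cfg=CFG, gene_sets=None, order=FILTER_ORDER):
    genotypes = {v.key: [GenotypeCall(patient, Gt.het)] for v in variants}
    gene_sets = gene_sets or _gene_sets({v.gene for v in variants})
    return prioritize_patient(patient, variants, genotypes, cfg, gene_sets, order)


class TestRecoveryPass:
    def test_mito_gene_failing_only_gerp_restored(self):
        v = make_variant(gene="MITO1", gerp=1.0)
        gs = _gene_sets({"MITO1"}, mito={"MITO1"})
        prioritized, traces = _run([v], gene_sets=gs)
        assert [x.key for x in prioritized] == [v.key]
        assert traces[v.key].status == "prioritized_recovery"

    def test_non_mito_gene_failing_gerp_stays_removed(self):
        v = make_variant(gene="OTHER1", gerp=1.0)
        prioritized, traces = _run([v])
        assert prioritized == []
        assert traces[v.key].status == "removed"

    def test_mito_gene_failing_maf_not_waived(self):
        v = make_variant(gene="MITO1", maf={"exac": 0.01})
        gs = _gene_sets({"MITO1"}, mito={"MITO1"})
        prioritized, traces = _run([v], gene_sets=gs)
        assert prioritized == []
        assert traces[v.key].status == "removed"


class TestCascade:
    def test_empty_input_empty_output(self):
        prioritized, traces = _run([])
        assert prioritized == [] and traces == {}

    def test_common_damaging_variant_removed_with_maf_reason(self):
        v = make_variant(maf={p: 0.3 for p in CFG.maf_max}, sift=0.0, gerp=6.0)
        _, traces = _run([v])
        trace = traces[v.key]
        assert trace.status == "removed"
        assert trace.entries[-1].filter_name.startswith("maf_")

    def test_trace_partition(self):
        rng = np.random.default_rng(0)
        variants = [_random_variant(rng, i) for i in range(200)]
        prioritized, traces = _run(variants)
        n_removed = sum(1 for t in traces.values() if t.status == "removed")
        assert len(prioritized) + n_removed == len(variants)

    def test_short_circuit_records_one_failure(self):
        v = make_variant(maf={"exac": 0.05}, sift=0.9, gerp=-1.0)
        _, traces = _run([v])
        failing = [e for e in traces[v.key].entries if not e.passed]
        assert len(failing) == 1


def _random_variant(rng, i):
    classes = ["missense", "nonsense", "splice_site", "frameshift_indel",
               "inframe_indel", "other"]
    maf = {}
    for panel, thr in CFG.maf_max.items():
        if rng.random() < 0.5:
            maf[panel] = float(min(0.5, rng.uniform(0, 3 * thr)))
    return AnnotatedVariant(
        key=VariantKey("chr1", 10_000 + i, "A", "G"),
        gene=f"G{i % 40:04d}" if i % 3 else f"M{i % 20:04d}",
        functional_class=classes[int(rng.integers(len(classes)))],
        maf=maf,
        sift=None if rng.random() < 0.2 else float(rng.uniform(0, 0.5)),
        gerp=None if rng.random() < 0.2 else float(rng.uniform(-2, 6)),
        in_segdup=bool(rng.random() < 0.1),
        case_allele_count=int(rng.integers(0, 13)),
        artifact_flag=bool(rng.random() < 0.05),
    )


class TestCascadeProperties:
    def test_order_invariance(self):
        """Final statuses are identical under permuted filter order."""
        rng = np.random.default_rng(42)
        variants = [_random_variant(rng, i) for i in range(300)]
        gs = _gene_sets({v.gene for v in variants},
                        mito={v.gene for v in variants if v.gene.startswith("M")})
        _, ref_traces = _run(variants, gene_sets=gs)
        ref = {k: t.status for k, t in ref_traces.items()}
        for _ in range(5):
            order = tuple(rng.permutation(FILTER_ORDER))
            _, traces = _run(variants, gene_sets=gs, order=order)
            assert {k: t.status for k, t in traces.items()} == ref

    def test_monotonicity_disabling_filters_never_shrinks_set(self):
        """The full cascade's prioritized set is contained in every
        reduced cascade's set (adding filters only removes)."""
        rng = np.random.default_rng(43)
        variants = [_random_variant(rng, i) for i in range(300)]
        gs = _gene_sets({v.gene for v in variants})
        full, _ = _run(variants, gene_sets=gs)
        full_keys = {v.key for v in full}
        for _ in range(5):
            disabled = frozenset(
                rng.choice(FILTER_ORDER, size=int(rng.integers(1, 5)), replace=False)
            )
            reduced_cfg = FilterConfig(disabled=disabled)
            reduced, _ = _run(variants, cfg=reduced_cfg, gene_sets=gs)
            assert full_keys <= {v.key for v in reduced}


def test_planted_causal_variants_all_survive(default_bundle, cohort_result):
    """Every planted causal nuclear variant is prioritized for its patient
    (sensitivity of the cascade on the default fixture)."""
    from mitodx.core import GenotypeCall as GC

    genotype_lists = {
        key: [GC(s, gt) for s, gt in d.items()]
        for key, d in default_bundle.genotypes.items()
    }
    for row in default_bundle.truth.to_dict(orient="records"):
        keys = [k for k in str(row["variant_keys"]).split(";") if k]
        if not keys:
            continue
        prioritized, _ = prioritize_patient(
            row["patient"], default_bundle.variants, genotype_lists,
            CFG, default_bundle.gene_sets,
        )
        got = {str(v.key) for v in prioritized}
        assert set(keys) <= got
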