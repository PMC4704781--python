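"""End-to-end diagnostic pipeline: run every analysis arm on a cohort bundle
and classify each patient.

Per patient the pipeline (i) runs the exome filter cascade and inheritance-
model reasoning on nuclear variants, (ii) screens mtDNA variants against the
pathogenicity catalog, calls large circular-genome deletions from coverage
and applies the qPCR depletion rule, (iii) segments array copy-number data,
prioritizes >100 kb segments against the control panel, detects LCSH and
composite CNV+SNV events, then (iv) combines all findings into a single
diagnostic category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .array_cnv import (
    CnvSegment,
    Probe,
    detect_composite_cnv_snv,
    detect_lcsh,
    prioritize_cnv,
    segment_copy_number,
)
from .classify import Finding, assign_firmness, classify_patient, summarize_cohort
from .core import GenotypeCall, Gt, VariantKey
from .inheritance import call_gene_inheritance
from .mtdna import CoverageProfile, call_depletion, detect_large_deletion, prioritize_mt_variants
from .prioritize import FilterConfig, prioritize_patient
from .simulate import CohortBundle


@dataclass
class PatientResult:
    patient: str
    findings: list[Finding]
    category: str
    lcsh_runs: list = field(default_factory=list)
    cnv_segments: list[CnvSegment] = field(default_factory=list)
    depletion: str | None = None


def _bed_rows_to_trees(rows) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in rows:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return trees


def _evidence_for(bundle: CohortBundle, patient: str, target: str) -> set[str]:
    return set(bundle.evidence.get((patient, target), set()))


def analyze_patient(
    bundle: CohortBundle,
    patient: str,
    cfg: FilterConfig,
    genotype_lists: dict[VariantKey, list[GenotypeCall]],
    control_cnv_trees: dict[str, IntervalTree],
    disorder_trees: dict[str, IntervalTree],
) -> PatientResult:
    findings: list[Finding] = []

    # ---- array arm (run first: LCSH supports nuclear findings) ----
    lcsh_runs: list = []
    kept_segments: list[CnvSegment] = []
    probes_df = bundle.probes.get(patient)
    if probes_df is not None:
        probes = [
            Probe(r.chrom, int(r.pos), r.genotype, float(r.log2_ratio))
            for r in probes_df.itertuples(index=False)
        ]
        autosomal = [p for p in probes if p.chrom != "chrX"]
        lcsh_runs = detect_lcsh(autosomal, min_mb=1.0)
        segments = segment_copy_number(probes)
        kept_segments = prioritize_cnv(segments, control_cnv_trees, disorder_trees)

    def lcsh_covers(gene: str) -> bool:
        chrom, gstart, gend = bundle.gene_regions[gene]
        return any(
            run.chrom == chrom and run.start <= gstart and run.end >= gend
            for run in lcsh_runs
        )

    # ---- nuclear arm ----
    prioritized, _traces = prioritize_patient(
        patient, bundle.variants, genotype_lists, cfg, bundle.gene_sets
    )
    by_gene: dict[str, list[tuple[VariantKey, Gt]]] = {}
    for v in prioritized:
        gt = bundle.genotype_of(patient, v.key)
        if gt is not None and gt.carries_alt():
            by_gene.setdefault(v.gene, []).append((v.key, gt))

    prioritized_gene_variants = {
        gene: [(str(k), gt.value) for k, gt in pairs] for gene, pairs in by_gene.items()
    }

    for gene, pairs in sorted(by_gene.items()):
        call = call_gene_inheritance(
            gene, patient, pairs, bundle.pedigree, bundle.genotype_of
        )
        if call is None:
            continue
        tags = _evidence_for(bundle, patient, gene)
        if call.model == "de_novo_dominant":
            tags.add("de_novo")
        if call.model == "hom_recessive" and lcsh_covers(gene):
            tags.add("lcsh_support")
        finding = Finding(
            patient=patient,
            source=bundle.gene_sets.source_of(gene),
            payload=call.variants,
            inheritance=call,
            evidence_tags=tags,
        )
        finding.firmness = assign_firmness(finding)
        findings.append(finding)

    # ---- composite CNV + SNV ----
    composite = detect_composite_cnv_snv(
        kept_segments, bundle.gene_regions, prioritized_gene_variants
    )
    nuclear_genes_called = {f.inheritance.gene for f in findings if f.inheritance}
    for comp in composite:
        if comp.gene in nuclear_genes_called:
            continue  # already biallelic on SNVs alone
        finding = Finding(
            patient=patient,
            source=bundle.gene_sets.source_of(comp.gene),
            payload=comp,
            evidence_tags=_evidence_for(bundle, patient, comp.gene),
            configuration_established=True,  # deletion + SNV hit both alleles
            notes=comp.note,
        )
        finding.firmness = assign_firmness(finding)
        findings.append(finding)

    # ---- chromosomal findings ----
    for seg in kept_segments:
        finding = Finding(
            patient=patient,
            source="chromosomal",
            payload=seg,
            evidence_tags=_evidence_for(bundle, patient, f"CNV:{seg.chrom}"),
        )
        finding.firmness = assign_firmness(finding)
        findings.append(finding)

    # ---- mtDNA arm ----
    for mv in prioritize_mt_variants(bundle.mt_variants.get(patient, []), bundle.mt_catalog):
        tags = {"known_pathogenic"} if mv.catalog_status == "confirmed" else set()
        finding = Finding(patient=patient, source="mtdna", payload=mv, evidence_tags=tags)
        finding.firmness = assign_firmness(finding)
        findings.append(finding)

    depth = bundle.mt_coverage.get(patient)
    if depth is not None:
        deletion = detect_large_deletion(CoverageProfile(depth))
        if deletion is not None:
            finding = Finding(
                patient=patient,
                source="mtdna",
                payload=deletion,
                evidence_tags=_evidence_for(bundle, patient, "MT:deletion"),
            )
            finding.firmness = assign_firmness(finding)
            findings.append(finding)

    depletion = None
    if patient in bundle.qpcr:
        ratios, control_mean = bundle.qpcr[patient]
        depletion = call_depletion(ratios, control_mean)

    return PatientResult(
        patient=patient,
        findings=findings,
        category=classify_patient(findings),
        lcsh_runs=lcsh_runs,
        cnv_segments=kept_segments,
        depletion=depletion,
    )


@dataclass
class CohortResult:
    patients: dict[str, PatientResult]
    summary: object

    def categories(self) -> dict[str, str]:
        return {p: r.category for p, r in self.patients.items()}


def run_cohort(bundle: CohortBundle, cfg: FilterConfig | None = None) -> CohortResult:
    """Analyze and classify every case in the bundle."""
    cfg = cfg or FilterConfig()
    genotype_lists = {
        key: [GenotypeCall(s, gt) for s, gt in d.items()]
        for key, d in bundle.genotypes.items()
    }
    # case-recurrence counts live on the variant annotations
    case_set = set(bundle.case_ids)
    for v in bundle.variants:
        d = bundle.genotypes.get(v.key, {})
        v.case_allele_count = sum(
            gt.alt_dose() for s, gt in d.items() if s in case_set
        )
    control_trees = _bed_rows_to_trees(bundle.control_cnv_bed)
    disorder_trees = _bed_rows_to_trees(bundle.disorder_bed)
    patients = {
        p: analyze_patient(bundle, p, cfg, genotype_lists, control_trees, disorder_trees)
        for p in bundle.case_ids
    }
    summary = summarize_cohort([r.category for r in patients.values()])
    return CohortResult(patients=patients, summary=summary)
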