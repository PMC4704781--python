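"""Whole-exome variant prioritization cascade.

The cascade keeps rare, protein-altering, case-specific, well-mapped,
predicted-deleterious variants. Each filter is an independent predicate on
one annotated variant (plus cohort-level allele counts), so the final status
of a variant is the conjunction of predicates and does not depend on
evaluation order; the order only determines which failure is *reported* in
the short-circuit trace.

A recovery pass restores variants in mitochondria-related genes that were
removed solely by the segmental-duplication, SIFT or GERP filters, on the
grounds that stringent mappability/deleteriousness filters may discard true
mutations in the gene set of primary biological interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import yaml

from .core import (
    FUNCTIONAL_CLASSES,
    MAF_PANELS,
    AnnotatedVariant,
    GeneSets,
    GenotypeCall,
    MitodxError,
    VariantKey,
)

#: Cascade order used for short-circuit trace reporting.
FILTER_ORDER = (
    "functional_class",
    "maf_dbsnp137",
    "maf_esp6500",
    "maf_1kg",
    "maf_exac",
    "maf_hgvd",
    "maf_1kjpn",
    "case_recurrence",
    "artifact",
    "segdup",
    "sift",
    "gerp",
)

#: Filters waived in the mitochondria-gene recovery pass.
RECOVERY_WAIVED = frozenset({"segdup", "sift", "gerp"})

#: Filters disabled in the simplified pipeline used for enrichment analysis
#: (manual inspection, validation bookkeeping, 1KJPN and HGVD panels).
SIMPLIFIED_DISABLED = frozenset({"artifact", "maf_hgvd", "maf_1kjpn"})


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the prioritization cascade.

    MAF thresholds are exclusive upper bounds: a variant is removed when a
    panel frequency *strictly exceeds* the panel threshold. ``case_allele_max``
    is the largest tolerated allele count among cases (exclusion at >= 10
    alleles means a maximum of 9).
    """

    maf_max: Mapping[str, float] = field(
        default_factory=lambda: {
            "dbsnp137": 0.010,
            "esp6500": 0.001,
            "1kg": 0.010,
            "exac": 0.001,
            "hgvd": 0.004,
            "1kjpn": 0.004,
        }
    )
    case_allele_max: int = 9
    sift_max: float = 0.15
    gerp_min: float = 2.5
    functional_classes: frozenset[str] = frozenset(
        {"nonsense", "splice_site", "frameshift_indel", "inframe_indel", "missense"}
    )
    kjpn_hom_veto: bool = False
    disabled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for panel, thr in self.maf_max.items():
            if not (0.0 <= thr <= 1.0):
                raise ValueError(f"MAF threshold for {panel} outside [0,1]")
        if not (0.0 <= self.sift_max <= 1.0):
            raise ValueError("sift_max outside [0,1]")
        unknown = set(self.disabled) - set(FILTER_ORDER)
        if unknown:
            raise ValueError(f"unknown filter names in disabled: {unknown}")

    def simplified(self) -> "FilterConfig":
        return replace(self, disabled=self.disabled | SIMPLIFIED_DISABLED)

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "maf_max" in data:
            data["maf_max"] = dict(data["maf_max"])
        if "functional_classes" in data:
            data["functional_classes"] = frozenset(data["functional_classes"])
        if "disabled" in data:
            data["disabled"] = frozenset(data["disabled"])
        return cls(**data)


@dataclass
class TraceEntry:
    filter_name: str
    passed: bool
    reason: str


@dataclass
class FilterTrace:
    """Audit record for one variant: short-circuit entries plus final status
    (prioritized_main | prioritized_recovery | removed)."""

    key: VariantKey
    entries: list[TraceEntry]
    status: str


# ---------------------------------------------------------------------------
# individual filter predicates (keep = True)
# ---------------------------------------------------------------------------

def filter_functional_class(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    if v.functional_class not in FUNCTIONAL_CLASSES:
        raise MitodxError(f"unknown functional class {v.functional_class!r} for {v.key}")
    if v.functional_class in cfg.functional_classes:
        return True, ""
    return False, f"class {v.functional_class} not protein-altering"


def filter_panel_frequency(v: AnnotatedVariant, panel: str, cfg: FilterConfig) -> tuple[bool, str]:
    """One population panel. Missing frequency means the variant is novel in
    that panel (frequency 0). dbSNP entries flagged with known medical impact
    are exempt from the dbSNP frequency filter."""
    freq = v.maf.get(panel, 0.0)
    if not (0.0 <= freq <= 1.0):
        raise MitodxError(f"frequency outside [0,1] for {v.key} in {panel}")
    if panel == "dbsnp137" and v.dbsnp_medical_impact:
        return True, ""
    if panel == "1kjpn" and cfg.kjpn_hom_veto and v.kjpn_hom:
        return False, "homozygote present in 1KJPN"
    if freq > cfg.maf_max[panel]:
        return False, f"MAF {freq:g} > {cfg.maf_max[panel]:g} in {panel}"
    return True, ""


def filter_population_frequency(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    """All panels at once; the reason names the first offending panel."""
    for panel in MAF_PANELS:
        keep, reason = filter_panel_frequency(v, panel, cfg)
        if not keep:
            return False, reason
    return True, ""


def filter_case_recurrence(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    if v.case_allele_count > cfg.case_allele_max:
        return False, f"{v.case_allele_count} alleles among cases (>= {cfg.case_allele_max + 1})"
    return True, ""


def filter_artifact(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    if v.artifact_flag:
        return False, "flagged as NGS artifact on manual inspection"
    return True, ""


def filter_segdup(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    if v.in_segdup:
        return False, "inside segmental duplication"
    return True, ""


def filter_sift(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    """Remove tolerated variants; a missing score never removes (SIFT is
    undefined for truncating variants, which the cascade must keep)."""
    if v.sift is not None and v.sift > cfg.sift_max:
        return False, f"SIFT {v.sift:g} > {cfg.sift_max:g} (tolerated)"
    return True, ""


def filter_gerp(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    if v.gerp is not None and v.gerp < cfg.gerp_min:
        return False, f"GERP {v.gerp:g} < {cfg.gerp_min:g} (unconserved)"
    return True, ""


def filter_deleteriousness(v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    keep, reason = filter_sift(v, cfg)
    if not keep:
        return keep, reason
    return filter_gerp(v, cfg)


def _predicate(name: str, v: AnnotatedVariant, cfg: FilterConfig) -> tuple[bool, str]:
    if name == "functional_class":
        return filter_functional_class(v, cfg)
    if name.startswith("maf_"):
        return filter_panel_frequency(v, name[4:], cfg)
    if name == "case_recurrence":
        return filter_case_recurrence(v, cfg)
    if name == "artifact":
        return filter_artifact(v, cfg)
    if name == "segdup":
        return filter_segdup(v, cfg)
    if name == "sift":
        return filter_sift(v, cfg)
    if name == "gerp":
        return filter_gerp(v, cfg)
    raise MitodxError(f"unknown filter {name}")


def evaluate_all(v: AnnotatedVariant, cfg: FilterConfig) -> dict[str, tuple[bool, str]]:
    """Outcome of every enabled predicate (independent of order)."""
    return {
        name: _predicate(name, v, cfg)
        for name in FILTER_ORDER
        if name not in cfg.disabled
    }


def recovery_pass(
    outcomes: Mapping[VariantKey, Mapping[str, tuple[bool, str]]],
    variants: Mapping[VariantKey, AnnotatedVariant],
    gene_sets: GeneSets,
) -> set[VariantKey]:
    """Variants in mitochondria-related genes removed *only* by waived
    (segdup/SIFT/GERP) filters."""
    restored = set()
    for key, outcome in outcomes.items():
        failing = {name for name, (keep, _) in outcome.items() if not keep}
        if not failing:
            continue  # survived main pass; nothing to recover
        if failing <= RECOVERY_WAIVED and variants[key].gene in gene_sets.mito_related_genes:
            restored.add(key)
    return restored


def prioritize_patient(
    patient_id: str,
    variants: Iterable[AnnotatedVariant],
    genotypes: Mapping[VariantKey, list[GenotypeCall]],
    cfg: FilterConfig,
    gene_sets: GeneSets,
    order: tuple[str, ...] = FILTER_ORDER,
) -> tuple[list[AnnotatedVariant], dict[VariantKey, FilterTrace]]:
    """Run the cascade on one patient's carried variants.

    Returns the prioritized variants (main-pass survivors plus recovery
    restorations) and a per-variant :class:`FilterTrace`. ``order`` affects
    only the reported short-circuit reason, never the outcome.
    """
    if set(order) != set(FILTER_ORDER):
        raise MitodxError("filter order must be a permutation of FILTER_ORDER")
    carried = []
    for v in variants:
        calls = genotypes.get(v.key, [])
        gt = next((c.gt for c in calls if c.sample_id == patient_id), None)
        if gt is not None and gt.carries_alt():
            carried.append(v)

    traces: dict[VariantKey, FilterTrace] = {}
    prioritized: list[AnnotatedVariant] = []
    outcomes = {v.key: evaluate_all(v, cfg) for v in carried}
    by_key = {v.key: v for v in carried}
    restored = recovery_pass(outcomes, by_key, gene_sets)
    for v in carried:
        outcome = outcomes[v.key]
        entries: list[TraceEntry] = []
        status = "prioritized_main"
        for name in order:
            if name not in outcome:
                continue
            keep, reason = outcome[name]
            entries.append(TraceEntry(name, keep, reason))
            if not keep:
                status = "removed"
                break
        if status == "removed" and v.key in restored:
            status = "prioritized_recovery"
        traces[v.key] = FilterTrace(v.key, entries, status)
        if status != "removed":
            prioritized.append(v)
    return prioritized, traces


def traces_to_frame(traces: Mapping[VariantKey, FilterTrace]):
    """Tab-delimited-ready audit table (variant, per-filter outcome, status)."""
    import pandas as pd

    rows = []
    for key, trace in traces.items():
        row = {"variant": str(key), "status": trace.status}
        for entry in trace.entries:
            row[entry.filter_name] = "pass" if entry.passed else f"fail: {entry.reason}"
        rows.append(row)
    return pd.DataFrame(rows)
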