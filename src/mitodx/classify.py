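"""Per-patient diagnostic synthesis: enzyme-deficiency severity, evidence-
based firmness (firm vs pVUS), the diagnostic category, and cohort summary
bookkeeping.

A finding is *firm* only when a qualifying genotype configuration is
established AND at least one piece of molecular evidence supports
pathogenicity; a cascade-surviving candidate without such evidence stays a
prioritized variant of unknown significance (pVUS) even in a gene already
reported as disease-causing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .core import MitodxError, PatientRecord
from .inheritance import InheritanceCall

EVIDENCE_TAGS = frozenset(
    {
        "rescue",
        "segregation",
        "de_novo",
        "known_pathogenic",
        "lcsh_support",
        "shared_rare_variant",
        "no_detectable_protein",
        "functional_assay",
        "splice_defect",
    }
)

#: Categories in default priority order (highest first); pvus_only and
#: unresolved are fallbacks, never "highest priority" picks.
CATEGORY_PRIORITY = (
    "mtdna_mutation",
    "known_nuclear_gene",
    "novel_mito_related_gene",
    "other_monogenic_gene",
    "chromosomal_aberration",
)
ALL_CATEGORIES = CATEGORY_PRIORITY + ("pvus_only", "unresolved")

_SOURCE_TO_CATEGORY = {
    "mtdna": "mtdna_mutation",
    "nuclear_known_gene": "known_nuclear_gene",
    "nuclear_mito_related": "novel_mito_related_gene",
    "nuclear_other_monogenic": "other_monogenic_gene",
    "chromosomal": "chromosomal_aberration",
}


@dataclass
class Finding:
    """One candidate diagnosis for one patient."""

    patient: str
    source: str  # mtdna | nuclear_known_gene | nuclear_mito_related | nuclear_other_monogenic | chromosomal
    payload: object = None  # variants / CnvSegment / MtVariant / MtDeletion
    inheritance: InheritanceCall | None = None
    evidence_tags: set[str] = field(default_factory=set)
    firmness: str = "pVUS"
    configuration_established: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.source not in _SOURCE_TO_CATEGORY:
            raise MitodxError(f"unknown finding source {self.source!r}")
        bad = self.evidence_tags - EVIDENCE_TAGS
        if bad:
            raise MitodxError(f"unknown evidence tags {bad}")

    @property
    def category(self) -> str:
        return _SOURCE_TO_CATEGORY[self.source]


def round_pct(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (bookkeeping convention)."""
    if total <= 0:
        raise MitodxError("total must be positive")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


# ---------------------------------------------------------------------------
# severity (residual enzyme activity, percent of control relative to citrate
# synthase or complex II activity)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeverityCriteria:
    major_tissue: float = 20.0
    major_fibroblast: float = 30.0
    major_two_tissues: float = 30.0
    minor_tissue: float = 30.0
    minor_fibroblast: float = 40.0
    minor_two_tissues: float = 40.0


def classify_severity(
    patient: PatientRecord, criteria: SeverityCriteria = SeverityCriteria()
) -> str:
    """major | minor | none under the residual-activity thresholds.

    Major: <20% in a tissue, <30% in a fibroblast cell line, or <30% in >=2
    tissues; minor: <30% / <40% / <40% respectively.
    """
    if not patient.enzyme_activities:
        raise MitodxError(f"no enzyme measurements for {patient.sample_id}")

    def meets(tissue_thr: float, fibro_thr: float, two_thr: float) -> bool:
        tissues_below: set[str] = set()
        for tissue, _cplx, pct in patient.enzyme_activities:
            if tissue == "fibroblast":
                if pct < fibro_thr:
                    return True
            elif pct < tissue_thr:
                return True
            if pct < two_thr:
                tissues_below.add(tissue)
        return len(tissues_below) >= 2

    c = criteria
    if meets(c.major_tissue, c.major_fibroblast, c.major_two_tissues):
        return "major"
    if meets(c.minor_tissue, c.minor_fibroblast, c.minor_two_tissues):
        return "minor"
    return "none"


# ---------------------------------------------------------------------------
# firmness and category
# ---------------------------------------------------------------------------

def configuration_established(finding: Finding) -> bool:
    """Biallelic / hemizygous / de-novo-dominant configuration established,
    with phase resolved for compound heterozygotes."""
    if finding.source == "mtdna":
        return True  # the mtDNA event itself is the configuration
    if finding.source == "chromosomal":
        return True  # directly observed segment
    call = finding.inheritance
    if call is None:
        return finding.configuration_established
    if call.model == "compound_het":
        return call.phase == "in_trans"
    return call.model in ("hom_recessive", "x_hemizygous", "de_novo_dominant")


def assign_firmness(finding: Finding) -> str:
    """firm iff the configuration is established and >= 1 molecular evidence
    tag supports pathogenicity; otherwise pVUS."""
    if configuration_established(finding) and finding.evidence_tags & EVIDENCE_TAGS:
        return "firm"
    return "pVUS"


def classify_patient(
    findings: Sequence[Finding],
    priority: Sequence[str] = CATEGORY_PRIORITY,
) -> str:
    """Category of the highest-priority firm finding; pvus_only when only
    pVUS findings exist; unresolved with no findings at all."""
    firm = [f for f in findings if f.firmness == "firm"]
    if firm:
        rank = {cat: i for i, cat in enumerate(priority)}
        return min(firm, key=lambda f: rank[f.category]).category
    if findings:
        return "pvus_only"
    return "unresolved"


# ---------------------------------------------------------------------------
# cohort bookkeeping
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    total: int
    counts: dict[str, int]
    percentages: dict[str, float]
    any_prioritized: int
    any_prioritized_pct: float
    firm_total: int
    firm_total_pct: float


def summarize_cohort(classifications: Iterable[str]) -> CohortSummary:
    """Per-category counts and half-up one-decimal percentages; derived
    aggregates: any_prioritized (everything except unresolved) and firm_total
    (all firm categories)."""
    cats = list(classifications)
    total = len(cats)
    if total == 0:
        raise MitodxError("empty cohort")
    unknown = set(cats) - set(ALL_CATEGORIES)
    if unknown:
        raise MitodxError(f"unknown categories {unknown}")
    counts = {cat: cats.count(cat) for cat in ALL_CATEGORIES}
    if sum(counts.values()) != total:
        raise MitodxError("category counts do not sum to cohort size")
    any_prio = total - counts["unresolved"]
    firm_total = sum(counts[c] for c in CATEGORY_PRIORITY)
    return CohortSummary(
        total=total,
        counts=counts,
        percentages={cat: round_pct(n, total) for cat, n in counts.items()},
        any_prioritized=any_prio,
        any_prioritized_pct=round_pct(any_prio, total),
        firm_total=firm_total,
        firm_total_pct=round_pct(firm_total, total),
    )


def breakdown(counts: Mapping[str, int], total: int) -> dict[str, tuple[int, float]]:
    """Generic count/percentage breakdown with the same rounding convention
    (used e.g. for the enzymatic-diagnosis summary)."""
    return {label: (n, round_pct(n, total)) for label, n in counts.items()}
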