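"""Genotype-configuration reasoning on prioritized variants.

Determines, per gene and patient, whether the surviving variants form a
qualifying Mendelian configuration: homozygous recessive, compound
heterozygous (in trans), X-linked hemizygous in a male, or a de novo
dominant heterozygote. A single inherited autosomal heterozygote is
inconsistent with recessive disease and is rejected unless trio data prove
it arose de novo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core import Gt, Pedigree, VariantKey

log = logging.getLogger(__name__)

X_CHROMS = {"X", "chrX"}


@dataclass
class PhaseCall:
    phase: str  # in_trans | in_cis | unknown
    mendelian_consistent: bool = True


@dataclass
class InheritanceCall:
    gene: str
    model: str  # hom_recessive | compound_het | x_hemizygous | de_novo_dominant | unresolved
    variants: list[VariantKey]
    phase: str = "unknown"  # in_trans | in_cis | unknown
    segregation: str = "untested"  # consistent | inconsistent | untested

    def __post_init__(self) -> None:
        if self.model == "compound_het":
            if len(self.variants) < 2:
                raise ValueError("compound_het requires >= 2 variants")
            if self.phase == "in_cis":
                raise ValueError("compound_het cannot be in cis")


def coerce_male_x(gt: Gt, chrom: str, is_male: bool) -> Gt:
    """Heterozygous calls on the male X are dialect artifacts; coerce to
    hemizygous with a warning."""
    if is_male and chrom in X_CHROMS and gt == Gt.het:
        log.warning("het call on male X coerced to hemizygous")
        return Gt.hemi_alt
    return gt


def check_recessive_consistency(
    gene: str,
    patient_genotypes: Sequence[tuple[VariantKey, Gt]],
    sex: str,
) -> str:
    """Candidate inheritance model for one gene's prioritized variants, or
    ``reject`` when only a single inherited autosomal heterozygote remains.

    De novo evidence is assessed separately (see :func:`detect_de_novo`);
    a de novo heterozygote bypasses the recessive-consistency rejection.
    """
    is_male = sex == "male"
    coerced = [(k, coerce_male_x(gt, k.chrom, is_male)) for k, gt in patient_genotypes]
    carrying = [(k, gt) for k, gt in coerced if gt.carries_alt()]
    if not carrying:
        return "reject"
    if any(gt == Gt.hom_alt for _, gt in carrying):
        return "hom_recessive"
    on_x = all(k.chrom in X_CHROMS for k, _ in carrying)
    if is_male and on_x and any(gt == Gt.hemi_alt for _, gt in carrying):
        return "x_hemizygous"
    hets = [(k, gt) for k, gt in carrying if gt == Gt.het]
    if len(hets) >= 2:
        return "compound_het"
    return "reject"


def _can_transmit(gt1: int, gt2: int, hap: tuple[int, int]) -> bool:
    """Can a parent with alt-allele doses (gt1, gt2) at two sites transmit
    haplotype ``hap`` (alleles at site 1 and 2)? Recombination between the
    two intragenic sites is ignored."""
    for dose, allele in zip((gt1, gt2), hap):
        if allele == 1 and dose == 0:
            return False
        if allele == 0 and dose == 2:
            return False
    return True


def phase_compound_het(
    father_gts: tuple[int, int] | None,
    mother_gts: tuple[int, int] | None,
    phase_groups: tuple[str | None, str | None] = (None, None),
) -> PhaseCall:
    """Phase of a pair of heterozygous variants in a child.

    Parental genotypes are alt-allele doses (0/1/2) at the two sites.
    Molecular phase groups (from cloned gDNA/cDNA sequencing) take precedence
    over trio inference. Without parents or groups the phase is unknown;
    such pairs stay candidates but firmness is capped downstream.

    Trio inference asks which child haplotype configurations are producible:
    cis (both alts from one parent) and/or trans (one alt from each). If
    exactly one configuration is producible, that is the phase; if both are,
    the trio is uninformative; if neither is, transmission is Mendelian-
    inconsistent and the call is flagged rather than silently phased.
    """
    g1, g2 = phase_groups
    if g1 is not None and g2 is not None:
        return PhaseCall("in_cis" if g1 == g2 else "in_trans")
    if father_gts is None or mother_gts is None:
        return PhaseCall("unknown")

    f1, f2 = father_gts
    m1, m2 = mother_gts
    cis_possible = (
        _can_transmit(f1, f2, (1, 1)) and _can_transmit(m1, m2, (0, 0))
    ) or (
        _can_transmit(f1, f2, (0, 0)) and _can_transmit(m1, m2, (1, 1))
    )
    trans_possible = (
        _can_transmit(f1, f2, (1, 0)) and _can_transmit(m1, m2, (0, 1))
    ) or (
        _can_transmit(f1, f2, (0, 1)) and _can_transmit(m1, m2, (1, 0))
    )
    if not cis_possible and not trans_possible:
        log.warning("Mendelian-inconsistent transmission for compound-het pair")
        return PhaseCall("unknown", mendelian_consistent=False)
    if trans_possible and not cis_possible:
        return PhaseCall("in_trans")
    if cis_possible and not trans_possible:
        return PhaseCall("in_cis")
    return PhaseCall("unknown")


def detect_de_novo(
    child_gt: Gt, father_gt: Gt | None, mother_gt: Gt | None
) -> tuple[bool, str]:
    """True iff the child carries the alt allele and both genotyped parents
    are homozygous reference. Missing parent genotypes make the variant
    untestable (returns False with a reason)."""
    if father_gt is None or mother_gt is None or Gt.missing in (father_gt, mother_gt):
        return False, "parent genotype missing: untestable"
    if not child_gt.carries_alt():
        return False, "child does not carry the alternate allele"
    if father_gt == Gt.hom_ref and mother_gt == Gt.hom_ref:
        return True, ""
    return False, "allele present in a parent"


def check_segregation(
    qualifying: Mapping[str, bool],
    affected: Mapping[str, bool],
) -> str:
    """Family segregation of a gene-level configuration.

    ``qualifying[sample]`` says whether the relative carries the same
    qualifying genotype configuration as the proband; ``affected`` their
    disease status. Consistent iff every affected relative qualifies and no
    unaffected relative does; with no genotyped relatives, untested.
    """
    if not qualifying:
        return "untested"
    for sample, has_config in qualifying.items():
        if affected[sample] != has_config:
            return "inconsistent"
    return "consistent"


def call_gene_inheritance(
    gene: str,
    patient_id: str,
    gene_variants: Sequence[tuple[VariantKey, Gt]],
    pedigree: Pedigree | None,
    genotype_of,
    phase_group_of=None,
) -> InheritanceCall | None:
    """Assemble the inheritance call for one gene in one patient.

    ``genotype_of(sample_id, key)`` returns a :class:`Gt` or None;
    ``phase_group_of(sample_id, key)`` returns a molecular phase-group label
    or None. Returns None when no qualifying configuration exists.
    """
    sex = "unknown"
    trio = None
    if pedigree is not None and patient_id in pedigree:
        sex = pedigree.members[patient_id].sex
        trio = pedigree.trio(patient_id)

    model = check_recessive_consistency(gene, gene_variants, sex)
    carrying = [
        (k, coerce_male_x(gt, k.chrom, sex == "male"))
        for k, gt in gene_variants
    ]
    carrying = [(k, gt) for k, gt in carrying if gt.carries_alt()]

    if model == "reject":
        # de novo bypass: a confirmed de novo heterozygote is retained as a
        # dominant candidate even though it fails the recessive model
        if trio is not None and len(carrying) == 1:
            key, gt = carrying[0]
            father, mother = trio
            is_dn, _ = detect_de_novo(gt, genotype_of(father, key), genotype_of(mother, key))
            if is_dn:
                return InheritanceCall(gene, "de_novo_dominant", [key])
        return None

    if model == "hom_recessive":
        keys = [k for k, gt in carrying if gt == Gt.hom_alt]
        return InheritanceCall(gene, "hom_recessive", keys)

    if model == "x_hemizygous":
        keys = [k for k, gt in carrying if gt == Gt.hemi_alt]
        return InheritanceCall(gene, "x_hemizygous", keys)

    # compound het: find a pair not proven in cis
    keys = [k for k, gt in carrying if gt == Gt.het]
    best: tuple[str, list[VariantKey]] | None = None
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            k1, k2 = keys[i], keys[j]
            parents: tuple = (None, None)
            if trio is not None:
                father, mother = trio
                fg = tuple(
                    (genotype_of(father, k) or Gt.missing).alt_dose() for k in (k1, k2)
                )
                mg = tuple(
                    (genotype_of(mother, k) or Gt.missing).alt_dose() for k in (k1, k2)
                )
                fmiss = any((genotype_of(father, k) or Gt.missing) == Gt.missing for k in (k1, k2))
                mmiss = any((genotype_of(mother, k) or Gt.missing) == Gt.missing for k in (k1, k2))
                parents = (None if fmiss else fg, None if mmiss else mg)
            groups = (None, None)
            if phase_group_of is not None:
                groups = (phase_group_of(patient_id, k1), phase_group_of(patient_id, k2))
            call = phase_compound_het(parents[0], parents[1], groups)
            if call.phase == "in_trans":
                return InheritanceCall(gene, "compound_het", [k1, k2], phase="in_trans")
            if call.phase == "unknown" and best is None:
                best = ("unknown", [k1, k2])
    if best is not None:
        return InheritanceCall(gene, "compound_het", best[1], phase="unknown")
    return None  # every pair proven in cis
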