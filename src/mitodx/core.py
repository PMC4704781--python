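"""Shared data types and readers/writers for the formats every pipeline stage touches.

Coordinate conventions: variants are 1-based inclusive (VCF); region files
(BED) are 0-based half-open. Conversion happens only at the reader boundary —
everything downstream of a reader speaks 1-based positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: MAF panels the prioritizer knows about, in cascade order.
MAF_PANELS = ("dbsnp137", "esp6500", "1kg", "exac", "hgvd", "1kjpn")

_ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "class",
    "maf_dbsnp137", "maf_esp6500", "maf_1kg", "maf_exac", "maf_hgvd",
    "maf_1kjpn", "sift", "gerp", "segdup",
]
_OPTIONAL_ANNOTATION_COLUMNS = ["dbsnp_medical_impact", "artifact_flag", "kjpn_hom"]

FUNCTIONAL_CLASSES = frozenset(
    {"nonsense", "splice_site", "frameshift_indel", "inframe_indel", "missense", "other"}
)


class MitodxError(Exception):
    """Base class for pipeline errors."""


class VcfParseError(MitodxError):
    pass


class PedigreeError(MitodxError):
    pass


class AnnotationError(MitodxError):
    pass


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a nuclear variant (chrom, 1-based pos, ref, alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) is not a variant")

    def __str__(self) -> str:  # used in traces and reports
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def parse(cls, text: str) -> "VariantKey":
        chrom, pos, change = text.split(":")
        ref, alt = change.split(">")
        return cls(chrom, int(pos), ref, alt)


@dataclass
class AnnotatedVariant:
    """One nuclear variant with the annotations the filter cascade consumes.

    ``maf`` maps panel name (see :data:`MAF_PANELS`) to a frequency in [0, 1];
    a panel absent from the map means the variant was not observed there and
    is treated as frequency 0 (novel). ``sift``/``gerp`` may be None (e.g.
    SIFT is undefined for truncating variants).
    """

    key: VariantKey
    gene: str
    functional_class: str
    maf: dict[str, float] = field(default_factory=dict)
    sift: float | None = None
    gerp: float | None = None
    in_segdup: bool = False
    case_allele_count: int = 0
    dbsnp_medical_impact: bool = False
    artifact_flag: bool = False
    kjpn_hom: bool = False

    def __post_init__(self) -> None:
        for panel, freq in self.maf.items():
            if not (0.0 <= freq <= 1.0):
                raise ValueError(f"MAF for panel {panel} outside [0,1]: {freq}")
        if self.case_allele_count < 0:
            raise ValueError("case_allele_count must be non-negative")


class Gt(str, Enum):
    """Zygosity vocabulary (hemi_alt only on X/Y/MT or male X)."""

    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    hemi_alt = "hemi_alt"
    missing = "missing"

    def alt_dose(self) -> int:
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "hemi_alt": 1, "missing": 0}[self.value]

    def carries_alt(self) -> bool:
        return self in (Gt.het, Gt.hom_alt, Gt.hemi_alt)


@dataclass
class GenotypeCall:
    sample_id: str
    gt: Gt
    phase_group: str | None = None


@dataclass
class Individual:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "male" | "female" | "unknown"
    affected: bool


class Pedigree:
    """PED-file pedigree with trio lookup."""

    def __init__(self, members: Mapping[str, Individual]):
        self.members = dict(members)
        self._check()

    def _check(self) -> None:
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid not in self.members:
                    raise PedigreeError(
                        f"sample {ind.sample_id} references unknown parent {pid}"
                    )
        # no sample may be its own ancestor
        for sid in self.members:
            seen: set[str] = set()
            stack = [sid]
            while stack:
                cur = stack.pop()
                ind = self.members[cur]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is None:
                        continue
                    if pid == sid:
                        raise PedigreeError(f"cyclic parentage involving {sid}")
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def trio(self, child: str) -> tuple[str, str] | None:
        ind = self.members.get(child)
        if ind is None or ind.father_id is None or ind.mother_id is None:
            return None
        return ind.father_id, ind.mother_id

    def trios(self) -> list[tuple[str, str, str]]:
        out = []
        for sid in self.members:
            t = self.trio(sid)
            if t is not None:
                out.append((sid, t[0], t[1]))
        return out

    def is_male(self, sample_id: str) -> bool:
        return self.members[sample_id].sex == "male"

    def affected_ids(self) -> list[str]:
        return [s for s, i in self.members.items() if i.affected]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.members


@dataclass
class PatientRecord:
    """Clinical/biochemical record for one patient.

    ``enzyme_activities`` holds (tissue label, complex, percent-of-control)
    triples; activities are already normalised to citrate synthase (or
    complex II) activity. The tissue label "fibroblast" is special-cased by
    the severity classifier; any other label counts as a clinically affected
    tissue.
    """

    sample_id: str
    enzyme_activities: list[tuple[str, str, float]] = field(default_factory=list)
    clinical_dx: str = ""
    age_onset_days: int | None = None

    def __post_init__(self) -> None:
        for tissue, cplx, pct in self.enzyme_activities:
            if pct < 0:
                raise ValueError(f"negative percent-of-control for {tissue}/{cplx}")


@dataclass
class GeneSets:
    known_disease_genes: set[str]
    mito_related_genes: set[str]
    all_genes: set[str]

    def __post_init__(self) -> None:
        if not self.known_disease_genes <= self.all_genes:
            raise ValueError("known_disease_genes must be a subset of all_genes")
        if not self.mito_related_genes <= self.all_genes:
            raise ValueError("mito_related_genes must be a subset of all_genes")

    def source_of(self, gene: str) -> str:
        """Finding source label for a nuclear gene."""
        if gene in self.known_disease_genes:
            return "nuclear_known_gene"
        if gene in self.mito_related_genes:
            return "nuclear_mito_related"
        return "nuclear_other_monogenic"


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "t", "yes", "y")
    if x is None or pd.isna(x):
        return False
    return bool(int(x))


def read_annotation_table(path: str | Path) -> dict[VariantKey, AnnotatedVariant]:
    """Read the tab-delimited annotation table keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table missing columns: {missing}")
    out: dict[VariantKey, AnnotatedVariant] = {}
    for row in df.to_dict("records"):
        key = VariantKey(str(row["chrom"]), int(row["pos"]), row["ref"], row["alt"])
        if key in out:
            raise AnnotationError(f"annotation key collision for {key}")
        maf = {}
        for panel in MAF_PANELS:
            val = row.get(f"maf_{panel}")
            if val is not None and val != "" and pd.notna(val):
                maf[panel] = float(val)
        out[key] = AnnotatedVariant(
            key=key,
            gene=str(row["gene"]),
            functional_class=str(row["class"]),
            maf=maf,
            sift=float(row["sift"]) if pd.notna(row["sift"]) else None,
            gerp=float(row["gerp"]) if pd.notna(row["gerp"]) else None,
            in_segdup=_parse_bool(row["segdup"]),
            dbsnp_medical_impact=_parse_bool(row.get("dbsnp_medical_impact", False)),
            artifact_flag=_parse_bool(row.get("artifact_flag", False)),
            kjpn_hom=_parse_bool(row.get("kjpn_hom", False)),
        )
    return out


def _gt_from_alleles(alleles: Sequence[int], allele_index: int, chrom: str) -> Gt:
    observed = [a for a in alleles if a is not None]
    if not observed or all(a == -1 for a in observed):
        return Gt.missing
    dose = sum(1 for a in observed if a == allele_index)
    if len(observed) == 1:
        # haploid call (male X/Y, MT)
        return Gt.hemi_alt if dose == 1 else Gt.hom_ref
    if dose == 0:
        return Gt.hom_ref
    if dose >= 2:
        return Gt.hom_alt
    return Gt.het


def read_cohort_vcf(
    vcf_path: str | Path, annotation_path: str | Path
) -> tuple[list[AnnotatedVariant], dict[VariantKey, list[GenotypeCall]]]:
    """Read a multi-sample VCF plus its annotation table.

    Multi-allelic records are split into one :class:`AnnotatedVariant` per alt
    allele. Records with no matching annotation row are reported via a logged
    warning (never silently dropped).
    """
    from cyvcf2 import VCF

    annotations = read_annotation_table(annotation_path)
    variants: list[AnnotatedVariant] = []
    genotypes: dict[VariantKey, list[GenotypeCall]] = {}
    reader = VCF(str(vcf_path))
    samples = list(reader.samples)
    n_record = 0
    try:
        for record in reader:
            n_record += 1
            for j, alt in enumerate(record.ALT, start=1):
                key = VariantKey(record.CHROM, record.POS, record.REF, alt)
                ann = annotations.get(key)
                if ann is None:
                    log.warning("VCF record %s has no annotation row; excluded", key)
                    continue
                calls = [
                    GenotypeCall(s, _gt_from_alleles(g[:-1], j, record.CHROM))
                    for s, g in zip(samples, record.genotypes)
                ]
                variants.append(ann)
                genotypes[key] = calls
    except MitodxError:
        raise
    except Exception as exc:  # malformed record
        raise VcfParseError(f"malformed VCF record near record {n_record + 1}: {exc}") from exc
    finally:
        reader.close()
    return variants, genotypes


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 6-column PED file (fam, id, father, mother, sex, phenotype)."""
    members: dict[str, Individual] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"PED line {lineno}: expected 6 columns")
            _, sid, father, mother, sex, pheno = fields[:6]
            if sid in members:
                raise PedigreeError(f"PED line {lineno}: duplicate sample {sid}")
            members[sid] = Individual(
                sample_id=sid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                affected=pheno == "2",
            )
    return Pedigree(members)


def read_gene_list(path: str | Path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED file (0-based half-open) into per-chromosome interval trees.

    Interval data holds the 4th column (name) when present.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    return trees


def bed_overlaps(trees: Mapping[str, IntervalTree], chrom: str, pos: int) -> bool:
    """1-based position against 0-based half-open trees."""
    tree = trees.get(chrom)
    return bool(tree is not None and tree.overlaps(pos - 1))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_vcf(
    path: str | Path,
    records: Iterable[tuple[VariantKey, dict[str, str]]],
    samples: Sequence[str],
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write a minimal biallelic multi-sample VCF.

    ``records`` yields (key, {sample_id: GT string}); absent samples default
    to 0/0. Records must be supplied pre-sorted.
    """
    records = list(records)
    if contigs is None:
        contigs = {}
        for key, _ in records:
            contigs[key.chrom] = max(contigs.get(key.chrom, 0), key.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for key, gts in records:
            cols = [key.chrom, str(key.pos), ".", key.ref, key.alt, ".", "PASS", ".", "GT"]
            cols += [gts.get(s, "0/0") for s in samples]
            fh.write("\t".join(cols) + "\n")


def write_annotation_table(
    path: str | Path, variants: Iterable[AnnotatedVariant]
) -> None:
    rows = []
    for v in variants:
        row = {
            "chrom": v.key.chrom, "pos": v.key.pos, "ref": v.key.ref, "alt": v.key.alt,
            "gene": v.gene, "class": v.functional_class,
        }
        for panel in MAF_PANELS:
            row[f"maf_{panel}"] = v.maf.get(panel, "")
        row.update(
            sift="" if v.sift is None else v.sift,
            gerp="" if v.gerp is None else v.gerp,
            segdup=int(v.in_segdup),
            dbsnp_medical_impact=int(v.dbsnp_medical_impact),
            artifact_flag=int(v.artifact_flag),
            kjpn_hom=int(v.kjpn_hom),
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def gt_to_vcf_string(gt: Gt, haploid: bool = False) -> str:
    if haploid:
        return {"hom_ref": "0", "hemi_alt": "1", "hom_alt": "1",
                "het": "1", "missing": "."}[gt.value]
    return {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
            "hemi_alt": "1", "missing": "./."}[gt.value]


def compute_case_allele_counts(
    genotypes: Mapping[VariantKey, list[GenotypeCall]], case_ids: set[str]
) -> dict[VariantKey, int]:
    """Allele counts among cases (het→1, hom_alt→2, hemi_alt→1)."""
    out = {}
    for key, calls in genotypes.items():
        out[key] = sum(c.gt.alt_dose() for c in calls if c.sample_id in case_ids)
    return out
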