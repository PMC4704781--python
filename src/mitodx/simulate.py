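"""Synthetic cohort generator with planted causal mechanisms.

Generates a fully synthetic patient cohort — nuclear variants with
population-panel annotations, trio pedigrees, SNP-array probe data, mtDNA
variant/coverage tables, qPCR copy-ratio tables — together with a truth
table, so that every downstream stage of the pipeline can be exercised and
scored without any external data.

Each planted mechanism is embedded consistently across files: a recessive
founder patient carries the founder allele homozygously, both parents are
heterozygous carriers in the VCF and PED, and the patient's array genotypes
are homozygous across a long stretch around the gene; an X-hemizygous plant
occurs only in a male patient; a CNV+SNV composite plant pairs a
heterozygous array deletion with a heterozygous variant in the overlapped
gene.

The generator emulates the statistical structure of a rare-disease cohort,
not its biology: background variants are independent across individuals
(no linkage disequilibrium), restricted to autosomes, and limited to one
per gene per individual so that undiagnosed patients are deterministically
unresolved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnnotatedVariant,
    GeneSets,
    Gt,
    Individual,
    MitodxError,
    Pedigree,
    VariantKey,
    gt_to_vcf_string,
    write_annotation_table,
    write_vcf,
)
from .mtdna import RCRS_LENGTH, CoverageProfile, circular_positions
from .prioritize import FilterConfig

BASES = np.array(list("ACGT"))

MECHANISMS = frozenset(
    {
        "recessive_hom_founder_lcsh",
        "compound_het",
        "de_novo_dominant",
        "x_hemizygous",
        "mtdna_point",
        "mtdna_deletion",
        "mtdna_depletion",
        "cnv_deletion",
        "cnv_plus_snv",
        "none",
    }
)


# ---------------------------------------------------------------------------
# genome / gene model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeModel:
    """Synthetic genome: 22 autosomes plus X, each ``chrom_length`` bp, and a
    16,569-bp circular MT."""

    chrom_length: int = 10_000_000
    gene_length: int = 20_000

    @property
    def chromosomes(self) -> list[str]:
        return [f"chr{i}" for i in range(1, 23)] + ["chrX"]

    def lengths(self) -> dict[str, int]:
        d = {c: self.chrom_length for c in self.chromosomes}
        d["MT"] = RCRS_LENGTH
        return d


def build_gene_catalog(
    genome: GenomeModel, n_genes: int, n_known: int, n_mito: int
) -> tuple[dict[str, tuple[str, int, int]], GeneSets]:
    """Deterministic synthetic gene catalog.

    Genes are laid out round-robin across the 23 nuclear chromosomes. The
    first ``n_known`` symbols form the known OXPHOS disease-gene set and the
    next ``n_mito`` the mitochondria-related set, leaving a pool of other
    genes large enough for 908-gene random draws.
    """
    chroms = genome.chromosomes
    per_chrom = -(-n_genes // len(chroms))
    spacing = (genome.chrom_length - 200_000) // per_chrom
    if spacing <= genome.gene_length:
        raise MitodxError("gene model too dense for chromosome length")
    regions: dict[str, tuple[str, int, int]] = {}
    counters = {c: 0 for c in chroms}
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        idx = counters[chrom]
        counters[chrom] += 1
        start = 100_001 + idx * spacing
        regions[f"G{i + 1:04d}"] = (chrom, start, start + genome.gene_length - 1)
    names = list(regions)
    gene_sets = GeneSets(
        known_disease_genes=set(names[:n_known]),
        mito_related_genes=set(names[n_known : n_known + n_mito]),
        all_genes=set(names),
    )
    return regions, gene_sets


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """One planted causal mechanism applied to ``n_patients`` patients."""

    mechanism: str
    n_patients: int
    gene_pool: str = "known"  # known | mito | other (nuclear mechanisms)
    target_gene: str | None = None
    evidence: tuple[str, ...] = ()
    shared_founder: bool = False  # all patients share one gene + allele
    lcsh_mb: float = 2.8
    deletion_breakpoints: tuple[int, int] = (11359, 15068)  # mtDNA, rCRS
    cnv_chrom: str = "chr6"
    cnv_start: int = 2_000_001
    cnv_size: int = 1_675_000
    depletion_ratio: float = 0.2
    heteroplasmy_range: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise MitodxError(f"unknown mechanism {self.mechanism!r}")
        if self.n_patients < 0:
            raise MitodxError("n_patients must be non-negative")


def default_mechanisms() -> tuple[PlantSpec, ...]:
    """The study conditions of the default cohort: all nine causal mechanism
    classes, with evidence mirroring the kinds of molecular support seen in
    practice (complementation rescue, segregation, shared founder alleles,
    de novo confirmation, absent protein)."""
    return (
        PlantSpec("recessive_hom_founder_lcsh", 4, "known",
                  evidence=("shared_rare_variant", "rescue"), shared_founder=True),
        PlantSpec("compound_het", 3, "known", evidence=("rescue", "segregation")),
        PlantSpec("compound_het", 2, "known", evidence=()),  # candidates without support
        PlantSpec("de_novo_dominant", 2, "other", evidence=("known_pathogenic",)),
        PlantSpec("x_hemizygous", 2, "mito",
                  evidence=("rescue", "no_detectable_protein")),
        PlantSpec("mtdna_point", 3),
        PlantSpec("mtdna_deletion", 1, evidence=("known_pathogenic",)),
        PlantSpec("mtdna_depletion", 2, "known",
                  evidence=("segregation", "known_pathogenic")),
        PlantSpec("cnv_deletion", 2, evidence=("de_novo",),
                  cnv_chrom="chr6", cnv_start=2_000_001, cnv_size=1_675_000),
        PlantSpec("cnv_plus_snv", 1, "known", evidence=("rescue",)),
    )


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int = 48
    n_controls: int = 48
    n_genes: int = 5000
    n_known_genes: int = 150
    n_mito_genes: int = 1200
    genome: GenomeModel = GenomeModel()
    fraction_rare: float = 0.8  # of non-surviving background: 1-x fail on MAF
    panel_jitter_sd: float = 0.2  # lognormal sd linking panel frequencies
    background_rate: float = 1.5  # expected cascade-surviving variants / individual
    removed_rate: float = 8.0  # expected cascade-removed variants / individual
    probe_spacing: int = 20_000
    het_probe_rate: float = 0.35
    log2_noise_sd: float = 0.12
    mt_depth: float = 1500.0
    mt_deletion_depth_factor: float = 0.1
    mechanisms: tuple[PlantSpec, ...] = field(default_factory=default_mechanisms)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_genes) <= 0:
            raise MitodxError("cohort and gene counts must be positive")
        planted = sum(m.n_patients for m in self.mechanisms)
        if planted > self.n_cases:
            raise MitodxError(f"{planted} planted patients exceed n_cases={self.n_cases}")


# ---------------------------------------------------------------------------
# cohort bundle (the in-memory product; also what load_cohort reconstructs)
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    case_ids: list[str]
    control_ids: list[str]
    pedigree: Pedigree
    variants: list[AnnotatedVariant]
    genotypes: dict[VariantKey, dict[str, Gt]]  # sparse: carriers + parents of note
    gene_sets: GeneSets
    gene_regions: dict[str, tuple[str, int, int]]
    probes: dict[str, pd.DataFrame]  # per case: chrom, pos, genotype, log2_ratio
    mt_variants: dict[str, list]  # per case: list[MtVariant] (status unset)
    mt_coverage: dict[str, np.ndarray]
    qpcr: dict[str, tuple[list[float], float]]
    mt_catalog: dict[tuple[int, str, str], str]
    evidence: dict[tuple[str, str], set[str]]
    enzyme_activities: dict[str, list[tuple[str, str, float]]]
    segdup_bed: list[tuple[str, int, int, str]]
    control_cnv_bed: list[tuple[str, int, int, str]]
    disorder_bed: list[tuple[str, int, int, str]]
    truth: pd.DataFrame | None = None

    def genotype_of(self, sample: str, key: VariantKey) -> Gt | None:
        d = self.genotypes.get(key)
        if d is None:
            return None
        return d.get(sample, Gt.hom_ref)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def _random_allele_pair(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(BASES[ref]), str(BASES[alt])


def _rare_maf(rng: np.random.Generator) -> dict[str, float]:
    """Panel frequencies for a variant that passes every MAF filter: absent
    from some panels, well below threshold in the rest."""
    maf = {}
    for panel, thr in FilterConfig().maf_max.items():
        if rng.random() < 0.5:
            maf[panel] = float(rng.uniform(0.0, 0.5 * thr))
    return maf


def _common_maf(rng: np.random.Generator, jitter_sd: float) -> dict[str, float]:
    """Correlated panel frequencies for a common variant (fails the cascade:
    base frequency far above the strictest panel thresholds)."""
    base = 10 ** rng.uniform(-2, -0.5)
    return {
        panel: float(min(0.5, base * rng.lognormal(0.0, jitter_sd)))
        for panel in FilterConfig().maf_max
    }


class _CohortBuilder:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.gene_regions, self.gene_sets = build_gene_catalog(
            config.genome, config.n_genes, config.n_known_genes, config.n_mito_genes
        )
        self.variants: dict[VariantKey, AnnotatedVariant] = {}
        self.genotypes: dict[VariantKey, dict[str, Gt]] = {}
        self.used_positions: set[tuple[str, int]] = set()
        self.planted_genes: set[str] = set()
        self.evidence: dict[tuple[str, str], set[str]] = {}
        self.truth_rows: list[dict] = []
        self.mt_variants: dict[str, list] = {}
        self.mt_deletions: dict[str, tuple[int, int]] = {}
        self.depletion_patients: dict[str, float] = {}
        self.lcsh_plants: dict[str, list[tuple[str, int, int]]] = {}
        self.cnv_plants: dict[str, list[tuple[str, int, int]]] = {}

    # -- helpers ------------------------------------------------------------

    def _new_position(self, chrom: str, lo: int, hi: int) -> int:
        for _ in range(1000):
            pos = int(self.rng.integers(lo, hi + 1))
            if (chrom, pos) not in self.used_positions:
                self.used_positions.add((chrom, pos))
                return pos
        raise MitodxError("could not place variant (region saturated)")

    def _pick_gene(self, pool: str, x_linked: bool | None = None) -> str:
        if pool == "known":
            candidates = sorted(self.gene_sets.known_disease_genes)
        elif pool == "mito":
            candidates = sorted(self.gene_sets.mito_related_genes)
        else:
            candidates = sorted(
                self.gene_sets.all_genes
                - self.gene_sets.known_disease_genes
                - self.gene_sets.mito_related_genes
            )
        eligible = []
        for g in candidates:
            if g in self.planted_genes:
                continue
            on_x = self.gene_regions[g][0] == "chrX"
            if x_linked is True and not on_x:
                continue
            if x_linked is False and on_x:
                continue
            eligible.append(g)
        if not eligible:
            raise MitodxError(f"no eligible gene in pool {pool!r}")
        gene = eligible[int(self.rng.integers(len(eligible)))]
        self.planted_genes.add(gene)
        return gene

    def _make_variant(
        self,
        gene: str,
        functional_class: str = "missense",
        damaging: bool = True,
    ) -> AnnotatedVariant:
        chrom, start, end = self.gene_regions[gene]
        pos = self._new_position(chrom, start, end)
        ref, alt = _random_allele_pair(self.rng)
        sift = None
        gerp = float(self.rng.uniform(3.0, 6.0))
        if functional_class == "missense":
            sift = float(self.rng.uniform(0.0, 0.1)) if damaging else float(self.rng.uniform(0.3, 0.9))
        v = AnnotatedVariant(
            key=VariantKey(chrom, pos, ref, alt),
            gene=gene,
            functional_class=functional_class,
            maf=_rare_maf(self.rng),
            sift=sift,
            gerp=gerp,
        )
        self.variants[v.key] = v
        return v

    def _set_gt(self, key: VariantKey, sample: str, gt: Gt) -> None:
        self.genotypes.setdefault(key, {})[sample] = gt

    def _record_truth(self, patient, mechanism, target, keys, category) -> None:
        self.truth_rows.append(
            {
                "patient": patient,
                "mechanism": mechanism,
                "target": target,
                "variant_keys": ";".join(str(k) for k in keys),
                "expected_category": category,
            }
        )

    def _add_evidence(self, patient: str, target: str, tags: tuple[str, ...]) -> None:
        if tags:
            self.evidence.setdefault((patient, target), set()).update(tags)

    # -- mechanism planting --------------------------------------------------

    def plant(self, spec: PlantSpec, patients: list[str], sexes: dict[str, str]) -> None:
        m = spec.mechanism
        if m == "none":
            for p in patients:
                self._record_truth(p, m, "", [], "unresolved")
            return
        if m == "recessive_hom_founder_lcsh":
            gene = spec.target_gene or self._pick_gene(spec.gene_pool, x_linked=False)
            v = self._make_variant(gene)
            chrom, gstart, gend = self.gene_regions[gene]
            center = (gstart + gend) // 2
            half = int(spec.lcsh_mb * 1e6 / 2)
            window = (chrom, max(1, center - half), center + half)
            for p in patients:
                self._set_gt(v.key, p, Gt.hom_alt)
                self._set_gt(v.key, f"{p}_fa", Gt.het)
                self._set_gt(v.key, f"{p}_mo", Gt.het)
                self.lcsh_plants.setdefault(p, []).append(window)
                self._add_evidence(p, gene, spec.evidence)
                self._record_truth(p, m, gene, [v.key],
                                   self._nuclear_category(gene))
            return
        if m == "compound_het":
            for p in patients:
                gene = spec.target_gene or self._pick_gene(spec.gene_pool, x_linked=False)
                v1 = self._make_variant(gene)
                v2 = self._make_variant(gene, functional_class="frameshift_indel")
                self._set_gt(v1.key, p, Gt.het)
                self._set_gt(v1.key, f"{p}_fa", Gt.het)
                self._set_gt(v2.key, p, Gt.het)
                self._set_gt(v2.key, f"{p}_mo", Gt.het)
                self._add_evidence(p, gene, spec.evidence)
                category = (
                    self._nuclear_category(gene) if spec.evidence else "pvus_only"
                )
                self._record_truth(p, m, gene, [v1.key, v2.key], category)
            return
        if m == "de_novo_dominant":
            for p in patients:
                gene = spec.target_gene or self._pick_gene(spec.gene_pool, x_linked=False)
                v = self._make_variant(gene)
                self._set_gt(v.key, p, Gt.het)
                self._set_gt(v.key, f"{p}_fa", Gt.hom_ref)
                self._set_gt(v.key, f"{p}_mo", Gt.hom_ref)
                self._add_evidence(p, gene, spec.evidence)
                self._record_truth(p, m, gene, [v.key], self._nuclear_category(gene))
            return
        if m == "x_hemizygous":
            for p in patients:
                sexes[p] = "male"
                gene = spec.target_gene or self._pick_gene(spec.gene_pool, x_linked=True)
                v = self._make_variant(gene)
                self._set_gt(v.key, p, Gt.hemi_alt)
                self._set_gt(v.key, f"{p}_fa", Gt.hom_ref)
                self._set_gt(v.key, f"{p}_mo", Gt.het)
                self._add_evidence(p, gene, spec.evidence)
                self._record_truth(p, m, gene, [v.key], self._nuclear_category(gene))
            return
        if m == "mtdna_point":
            confirmed = sorted(k for k, s in self.mt_catalog.items() if s == "confirmed")
            for p in patients:
                pos, ref, alt = confirmed[int(self.rng.integers(len(confirmed)))]
                lo, hi = spec.heteroplasmy_range
                het = float(self.rng.uniform(lo, hi))
                self.mt_variants.setdefault(p, []).append((pos, ref, alt, het))
                self._record_truth(p, m, f"MT:{pos}", [], "mtdna_mutation")
            return
        if m == "mtdna_deletion":
            first, last = spec.deletion_breakpoints
            for p in patients:
                self.mt_deletions[p] = (first, last)
                self._add_evidence(p, "MT:deletion", spec.evidence)
                self._record_truth(p, m, f"MT:{first}-{last}", [], "mtdna_mutation")
            return
        if m == "mtdna_depletion":
            for p in patients:
                gene = spec.target_gene or self._pick_gene(spec.gene_pool, x_linked=False)
                v = self._make_variant(gene)
                self._set_gt(v.key, p, Gt.hom_alt)
                self._set_gt(v.key, f"{p}_fa", Gt.het)
                self._set_gt(v.key, f"{p}_mo", Gt.het)
                self.depletion_patients[p] = spec.depletion_ratio
                self._add_evidence(p, gene, spec.evidence)
                self._record_truth(p, m, gene, [v.key], self._nuclear_category(gene))
            return
        if m == "cnv_deletion":
            region = (spec.cnv_chrom, spec.cnv_start, spec.cnv_start + spec.cnv_size - 1)
            for p in patients:
                self.cnv_plants.setdefault(p, []).append(region)
                self._add_evidence(p, f"CNV:{spec.cnv_chrom}", spec.evidence)
                self._record_truth(
                    p, m, f"{region[0]}:{region[1]}-{region[2]}", [],
                    "chromosomal_aberration",
                )
            return
        if m == "cnv_plus_snv":
            for p in patients:
                gene = spec.target_gene or self._pick_gene(spec.gene_pool, x_linked=False)
                chrom, gstart, gend = self.gene_regions[gene]
                start = max(1, gstart - 500_000)
                region = (chrom, start, start + 1_387_000 - 1)
                v = self._make_variant(gene)
                self._set_gt(v.key, p, Gt.het)
                self._set_gt(v.key, f"{p}_mo", Gt.het)  # SNV from mother; CNV paternal
                self.cnv_plants.setdefault(p, []).append(region)
                self._add_evidence(p, gene, spec.evidence)
                self._record_truth(p, m, gene, [v.key], self._nuclear_category(gene))
            return
        raise MitodxError(f"unhandled mechanism {m}")

    def _nuclear_category(self, gene: str) -> str:
        return {
            "nuclear_known_gene": "known_nuclear_gene",
            "nuclear_mito_related": "novel_mito_related_gene",
            "nuclear_other_monogenic": "other_monogenic_gene",
        }[self.gene_sets.source_of(gene)]

    # -- background variants -------------------------------------------------

    def _background_genes(self, n: int) -> list[str]:
        # background is confined to autosomal genes outside the known-disease
        # and mitochondria-related sets, so the configured background_rate is
        # exactly the expected cascade-surviving count (variants in
        # mitochondria-related genes could otherwise re-enter through the
        # recovery pass) and undiagnosed patients stay unresolved
        pool = sorted(
            g for g, (chrom, _s, _e) in self.gene_regions.items()
            if chrom != "chrX"
            and g not in self.planted_genes
            and g not in self.gene_sets.known_disease_genes
            and g not in self.gene_sets.mito_related_genes
        )
        if n > 0 and not pool:
            raise MitodxError(
                "no eligible background genes: enlarge n_genes or shrink the "
                "known/mito gene subsets"
            )
        idx = self.rng.choice(len(pool), size=min(n, len(pool)), replace=False)
        return [pool[i] for i in sorted(idx)]

    def add_background(self, individual: str, has_parents: bool) -> None:
        cfg = self.cfg
        n_surv = int(self.rng.poisson(cfg.background_rate))
        n_rem = int(self.rng.poisson(cfg.removed_rate))
        genes = self._background_genes(n_surv + n_rem)
        for i, gene in enumerate(genes):
            surviving = i < n_surv
            if surviving:
                v = self._make_variant(gene)
            else:
                v = self._make_failing_variant(gene)
            self.planted_genes.discard(gene)  # background genes stay reusable
            self._set_gt(v.key, individual, Gt.het)
            if has_parents:
                parent = f"{individual}_fa" if self.rng.random() < 0.5 else f"{individual}_mo"
                self._set_gt(v.key, parent, Gt.het)

    def _make_failing_variant(self, gene: str) -> AnnotatedVariant:
        cfg = self.cfg
        if self.rng.random() >= cfg.fraction_rare:
            mode = "common"
        else:
            mode = ["other_class", "segdup", "tolerated", "unconserved", "artifact"][
                int(self.rng.integers(5))
            ]
        v = self._make_variant(gene)
        if mode == "common":
            v.maf = _common_maf(self.rng, cfg.panel_jitter_sd)
        elif mode == "other_class":
            v.functional_class = "other"
            v.sift = None
        elif mode == "segdup":
            v.in_segdup = True
        elif mode == "tolerated":
            v.sift = float(self.rng.uniform(0.3, 0.9))
        elif mode == "unconserved":
            v.gerp = float(self.rng.uniform(-2.0, 2.0))
        else:
            v.artifact_flag = True
        return v

    # -- per-sample auxiliary data -------------------------------------------

    def make_mt_catalog(self, n_confirmed: int = 15, n_reported: int = 15) -> None:
        catalog: dict[tuple[int, str, str], str] = {}
        while len(catalog) < n_confirmed + n_reported:
            pos = int(self.rng.integers(1, RCRS_LENGTH + 1))
            ref, alt = _random_allele_pair(self.rng)
            if (pos, ref, alt) not in catalog:
                status = "confirmed" if len(catalog) < n_confirmed else "reported"
                catalog[(pos, ref, alt)] = status
        self.mt_catalog = catalog

    def make_probes(self, sample: str, sex: str) -> pd.DataFrame:
        cfg = self.cfg
        frames = []
        lcsh = self.lcsh_plants.get(sample, [])
        cnvs = self.cnv_plants.get(sample, [])
        for chrom in cfg.genome.chromosomes:
            positions = np.arange(
                cfg.probe_spacing // 2, cfg.genome.chrom_length, cfg.probe_spacing
            )
            n = len(positions)
            hom = self.rng.random(n) >= cfg.het_probe_rate
            which_hom = self.rng.random(n) < 0.5
            genotype = np.where(hom, np.where(which_hom, "AA", "BB"), "AB")
            log2 = self.rng.normal(0.0, cfg.log2_noise_sd, size=n)
            if chrom == "chrX" and sex == "male":
                genotype = np.where(which_hom, "AA", "BB")
            for wchrom, wstart, wend in lcsh:
                if wchrom == chrom:
                    mask = (positions >= wstart) & (positions <= wend)
                    genotype = np.where(
                        mask, np.where(which_hom, "AA", "BB"), genotype
                    )
            for rchrom, rstart, rend in cnvs:
                if rchrom == chrom:
                    mask = (positions >= rstart) & (positions <= rend)
                    log2 = np.where(
                        mask, self.rng.normal(-1.0, cfg.log2_noise_sd, size=n), log2
                    )
                    # hemizygous region: genotypes collapse to homozygous calls
                    genotype = np.where(
                        mask, np.where(which_hom, "AA", "BB"), genotype
                    )
            frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": positions, "genotype": genotype,
                     "log2_ratio": np.round(log2, 4)}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def make_coverage(self, sample: str) -> np.ndarray:
        cfg = self.cfg
        depth = self.rng.poisson(cfg.mt_depth, size=RCRS_LENGTH).astype(float)
        if sample in self.mt_deletions:
            first, last = self.mt_deletions[sample]
            arc = circular_positions(first, last) - 1
            depth[arc] = self.rng.poisson(
                cfg.mt_depth * cfg.mt_deletion_depth_factor, size=len(arc)
            )
        return depth

    def make_mt_noise(self, sample: str) -> None:
        """Benign private mtDNA variants absent from the catalog."""
        for _ in range(2):
            while True:
                pos = int(self.rng.integers(1, RCRS_LENGTH + 1))
                ref, alt = _random_allele_pair(self.rng)
                if (pos, ref, alt) not in self.mt_catalog:
                    break
            het = float(self.rng.uniform(0.05, 1.0))
            self.mt_variants.setdefault(sample, []).append((pos, ref, alt, het))

    def make_qpcr(self, sample: str) -> tuple[list[float], float]:
        if sample in self.depletion_patients:
            mu = self.depletion_patients[sample]
            ratios = np.clip(self.rng.normal(mu, 0.02, size=4), 0.01, None)
        else:
            ratios = np.clip(self.rng.normal(1.0, 0.05, size=4), 0.5, None)
        return [round(float(r), 4) for r in ratios], 1.0

    def make_enzyme_activities(self, sample: str) -> list[tuple[str, str, float]]:
        cplx = ["I", "III", "IV"][int(self.rng.integers(3))]
        return [
            ("muscle", cplx, round(float(self.rng.uniform(5.0, 100.0)), 1)),
            ("fibroblast", cplx, round(float(self.rng.uniform(5.0, 100.0)), 1)),
        ]

    # -- fixed region files ----------------------------------------------------

    def make_beds(self) -> None:
        self.segdup_bed = [
            ("chr1", 500_000, 620_000, "segdup_1"),
            ("chr2", 4_000_000, 4_150_000, "segdup_2"),
            ("chr9", 7_200_000, 7_390_000, "segdup_3"),
        ]
        self.control_cnv_bed = [
            (f"chr{c}", s, s + size, f"ctrl_cnv_{i}")
            for i, (c, s, size) in enumerate(
                [(2, 1_000_000, 150_000), (3, 5_500_000, 250_000),
                 (5, 8_000_000, 120_000), (11, 300_000, 180_000),
                 (20, 6_000_000, 220_000)]
            )
        ]
        # known genomic-disorder regions covering the planted CNV geometries
        planted_regions = sorted(
            {r for plants in self.cnv_plants.values() for r in plants}
        )
        self.disorder_bed = [
            (chrom, max(0, start - 100_001), end + 100_000,
             f"genomic_disorder_region_{i + 1}")
            for i, (chrom, start, end) in enumerate(planted_regions)
        ]

    # -- assembly --------------------------------------------------------------

    def build(self) -> CohortBundle:
        cfg = self.cfg
        case_ids = [f"Case{i + 1:03d}" for i in range(cfg.n_cases)]
        control_ids = [f"Ctrl{i + 1:03d}" for i in range(cfg.n_controls)]
        sexes = {
            p: ("male" if self.rng.random() < 0.5 else "female") for p in case_ids
        }
        self.make_mt_catalog()

        # assign mechanisms to patients in order; the rest are 'none'
        cursor = 0
        assignments: list[tuple[PlantSpec, list[str]]] = []
        for spec in cfg.mechanisms:
            patients = case_ids[cursor : cursor + spec.n_patients]
            cursor += spec.n_patients
            assignments.append((spec, patients))
        none_spec = PlantSpec("none", cfg.n_cases - cursor)
        assignments.append((none_spec, case_ids[cursor:]))
        for spec, patients in assignments:
            self.plant(spec, patients, sexes)

        for p in case_ids:
            self.add_background(p, has_parents=True)
        for c in control_ids:
            self.add_background(c, has_parents=False)

        # pedigree: trios for cases, singleton controls
        members: dict[str, Individual] = {}
        for p in case_ids:
            fa, mo = f"{p}_fa", f"{p}_mo"
            members[fa] = Individual(fa, None, None, "male", False)
            members[mo] = Individual(mo, None, None, "female", False)
            members[p] = Individual(p, fa, mo, sexes[p], True)
        for c in control_ids:
            members[c] = Individual(c, None, None,
                                    "male" if self.rng.random() < 0.5 else "female",
                                    False)
        pedigree = Pedigree(members)

        self.make_beds()
        probes = {p: self.make_probes(p, sexes[p]) for p in case_ids}
        coverage = {p: self.make_coverage(p) for p in case_ids}
        for p in case_ids:
            self.make_mt_noise(p)
        qpcr = {p: self.make_qpcr(p) for p in case_ids}
        enzymes = {p: self.make_enzyme_activities(p) for p in case_ids}

        from .mtdna import MtVariant

        mt_variants = {
            p: [MtVariant(pos, ref, alt, het) for pos, ref, alt, het in rows]
            for p, rows in self.mt_variants.items()
        }

        variants = [self.variants[k] for k in sorted(self.variants)]
        truth = pd.DataFrame(self.truth_rows)
        return CohortBundle(
            case_ids=case_ids,
            control_ids=control_ids,
            pedigree=pedigree,
            variants=variants,
            genotypes=self.genotypes,
            gene_sets=self.gene_sets,
            gene_regions=self.gene_regions,
            probes=probes,
            mt_variants=mt_variants,
            mt_coverage=coverage,
            qpcr=qpcr,
            mt_catalog=self.mt_catalog,
            evidence=self.evidence,
            enzyme_activities=enzymes,
            segdup_bed=self.segdup_bed,
            control_cnv_bed=self.control_cnv_bed,
            disorder_bed=self.disorder_bed,
            truth=truth,
        )


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate the full synthetic cohort. Deterministic for a fixed seed."""
    return _CohortBuilder(config).build()


def plant_mtdna_deletion(
    start: int,
    end: int,
    depth_in: float,
    depth_out: float,
    profile_length: int = RCRS_LENGTH,
    rng: np.random.Generator | None = None,
) -> tuple[CoverageProfile, tuple[int, int]]:
    """Synthetic circular coverage profile with a planted deletion arc
    (Poisson noise; ``depth_out`` inside the arc, ``depth_in`` outside)."""
    if depth_in <= 0 or depth_out <= 0:
        raise MitodxError("depths must be positive")
    if rng is None:
        rng = np.random.default_rng()
    depth = rng.poisson(depth_in, size=profile_length).astype(float)
    arc = circular_positions(start, end, profile_length) - 1
    depth[arc] = rng.poisson(depth_out, size=len(arc))
    return CoverageProfile(depth), (start, end)


# ---------------------------------------------------------------------------
# writing / loading the on-disk cohort
# ---------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir: str | Path) -> None:
    """Write every file the pipeline readers consume, plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ped = bundle.pedigree

    samples = sorted(ped.members)
    records = []
    for key in sorted(bundle.genotypes):
        gts = {}
        for sample, gt in bundle.genotypes[key].items():
            haploid = key.chrom == "chrX" and ped.is_male(sample)
            gts[sample] = gt_to_vcf_string(gt, haploid=haploid)
        # explicit reference calls for everyone else, haploid on male X
        for sample in samples:
            if sample not in gts:
                haploid = key.chrom == "chrX" and ped.is_male(sample)
                gts[sample] = "0" if haploid else "0/0"
        records.append((key, gts))
    write_vcf(outdir / "cohort.vcf", records, samples)
    write_annotation_table(outdir / "annotations.tsv", bundle.variants)

    with open(outdir / "pedigree.ped", "w") as fh:
        for sid in samples:
            ind = ped.members[sid]
            fh.write(
                "\t".join(
                    [
                        "FAM" + sid.split("_")[0],
                        sid,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        {"male": "1", "female": "2"}.get(ind.sex, "0"),
                        "2" if ind.affected else "1",
                    ]
                )
                + "\n"
            )

    with open(outdir / "cohort_samples.tsv", "w") as fh:
        fh.write("sample\trole\n")
        for p in bundle.case_ids:
            fh.write(f"{p}\tcase\n")
        for c in bundle.control_ids:
            fh.write(f"{c}\tcontrol\n")

    probe_frames = []
    for sample, df in bundle.probes.items():
        df = df.copy()
        df.insert(0, "sample", sample)
        probe_frames.append(df)
    pd.concat(probe_frames, ignore_index=True).to_csv(
        outdir / "array_probes.tsv", sep="\t", index=False
    )

    mt_rows = []
    for sample, mvs in sorted(bundle.mt_variants.items()):
        for v in mvs:
            depth = 1000
            alt_count = int(round(v.heteroplasmy * depth))
            mt_rows.append(
                {"sample": sample, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                 "ref_count": depth - alt_count, "alt_count": alt_count}
            )
    pd.DataFrame(mt_rows).to_csv(outdir / "mt_variants.tsv", sep="\t", index=False)

    cov_frames = []
    for sample in bundle.case_ids:
        depth = bundle.mt_coverage[sample]
        cov_frames.append(
            pd.DataFrame(
                {"sample": sample, "pos": np.arange(1, len(depth) + 1),
                 "depth": depth.astype(int)}
            )
        )
    pd.concat(cov_frames, ignore_index=True).to_csv(
        outdir / "mt_coverage.tsv", sep="\t", index=False
    )

    pd.DataFrame(
        [
            {"pos": pos, "ref": ref, "alt": alt, "status": status}
            for (pos, ref, alt), status in sorted(bundle.mt_catalog.items())
        ]
    ).to_csv(outdir / "mt_catalog.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"sample": s, "tissue": "muscle", "rep1": r[0], "rep2": r[1],
             "rep3": r[2], "rep4": r[3], "control_mean": cm}
            for s, (r, cm) in sorted(bundle.qpcr.items())
        ]
    ).to_csv(outdir / "qpcr.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"sample": s, "tissue": t, "complex": c, "percent_of_control": pct}
            for s, acts in sorted(bundle.enzyme_activities.items())
            for t, c, pct in acts
        ]
    ).to_csv(outdir / "enzyme_activities.tsv", sep="\t", index=False)

    for name, rows in (
        ("segdup.bed", bundle.segdup_bed),
        ("control_cnvs.bed", bundle.control_cnv_bed),
        ("disorder_regions.bed", bundle.disorder_bed),
    ):
        with open(outdir / name, "w") as fh:
            for chrom, start, end, label in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")

    for name, genes in (
        ("genes_known.txt", bundle.gene_sets.known_disease_genes),
        ("genes_mito.txt", bundle.gene_sets.mito_related_genes),
        ("genes_all.txt", bundle.gene_sets.all_genes),
    ):
        with open(outdir / name, "w") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")

    pd.DataFrame(
        [
            {"gene": g, "chrom": c, "start": s, "end": e}
            for g, (c, s, e) in sorted(bundle.gene_regions.items())
        ]
    ).to_csv(outdir / "gene_regions.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"sample": s, "target": t, "tag": tag}
            for (s, t), tags in sorted(bundle.evidence.items())
            for tag in sorted(tags)
        ]
    ).to_csv(outdir / "evidence.tsv", sep="\t", index=False)

    if bundle.truth is not None:
        bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(bundle.truth.to_dict(orient="records"), fh, indent=1)


def load_cohort(indir: str | Path) -> CohortBundle:
    """Reconstruct a :class:`CohortBundle` from a written cohort directory."""
    from .core import read_cohort_vcf, read_gene_list, read_pedigree
    from .mtdna import read_coverage_table, read_mt_catalog, read_mt_variant_table, read_qpcr_table

    indir = Path(indir)
    pedigree = read_pedigree(indir / "pedigree.ped")
    roles = pd.read_csv(indir / "cohort_samples.tsv", sep="\t")
    case_ids = roles.loc[roles.role == "case", "sample"].tolist()
    control_ids = roles.loc[roles.role == "control", "sample"].tolist()

    variants, genotype_calls = read_cohort_vcf(
        indir / "cohort.vcf", indir / "annotations.tsv"
    )
    genotypes = {
        key: {c.sample_id: c.gt for c in calls}
        for key, calls in genotype_calls.items()
    }

    gene_sets = GeneSets(
        known_disease_genes=read_gene_list(indir / "genes_known.txt"),
        mito_related_genes=read_gene_list(indir / "genes_mito.txt"),
        all_genes=read_gene_list(indir / "genes_all.txt"),
    )
    regions_df = pd.read_csv(indir / "gene_regions.tsv", sep="\t")
    gene_regions = {
        r.gene: (r.chrom, int(r.start), int(r.end))
        for r in regions_df.itertuples(index=False)
    }

    probes_df = pd.read_csv(
        indir / "array_probes.tsv", sep="\t",
        dtype={"sample": str, "chrom": str, "genotype": str},
    )
    probes = {
        str(sample): grp.drop(columns="sample").reset_index(drop=True)
        for sample, grp in probes_df.groupby("sample", sort=False)
    }

    coverage = {
        s: prof.depth for s, prof in read_coverage_table(indir / "mt_coverage.tsv").items()
    }

    evidence_df = pd.read_csv(indir / "evidence.tsv", sep="\t")
    evidence: dict[tuple[str, str], set[str]] = {}
    for row in evidence_df.itertuples(index=False):
        evidence.setdefault((row.sample, row.target), set()).add(row.tag)

    enzymes_df = pd.read_csv(indir / "enzyme_activities.tsv", sep="\t")
    enzymes: dict[str, list[tuple[str, str, float]]] = {}
    for row in enzymes_df.itertuples(index=False):
        enzymes.setdefault(row.sample, []).append(
            (row.tissue, str(getattr(row, "complex")), float(row.percent_of_control))
        )

    def _read_bed_rows(name):
        rows = []
        with open(indir / name) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else ""))
        return rows

    truth = None
    if (indir / "truth.tsv").exists():
        truth = pd.read_csv(indir / "truth.tsv", sep="\t").fillna("")

    return CohortBundle(
        case_ids=case_ids,
        control_ids=control_ids,
        pedigree=pedigree,
        variants=variants,
        genotypes=genotypes,
        gene_sets=gene_sets,
        gene_regions=gene_regions,
        probes=probes,
        mt_variants=read_mt_variant_table(indir / "mt_variants.tsv"),
        mt_coverage=coverage,
        qpcr=read_qpcr_table(indir / "qpcr.tsv"),
        mt_catalog=read_mt_catalog(indir / "mt_catalog.tsv"),
        evidence=evidence,
        enzyme_activities=enzymes,
        segdup_bed=_read_bed_rows("segdup.bed"),
        control_cnv_bed=_read_bed_rows("control_cnvs.bed"),
        disorder_bed=_read_bed_rows("disorder_regions.bed"),
        truth=truth,
    )
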