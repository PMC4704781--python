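"""Case-control evaluation of the prioritization pipeline: percentage of
individuals harboring prioritized genes for known OXPHOS disease genes,
mitochondria-related genes, and a resampled random-gene-set null.

The evaluation runs a simplified cascade (no manual-inspection, validation,
1KJPN or HGVD steps — the last because control cohorts typically contribute
to the Japanese reference panels being filtered against). The null draws
random gene sets (default 908 genes, 1000 draws) from the gene pool after
excluding known disease genes and mitochondria-related genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .core import AnnotatedVariant, GeneSets, GenotypeCall, Gt, MitodxError, Pedigree, VariantKey
from .inheritance import call_gene_inheritance
from .prioritize import FilterConfig, prioritize_patient


@dataclass(frozen=True)
class EnrichmentConfig:
    random_set_size: int = 908
    n_draws: int = 1000
    seed: int = 0
    simplified: bool = True
    require_configuration: bool = True


@dataclass
class EnrichmentResult:
    pct_cases: float
    pct_controls: float
    fold: float | None
    null_mean: float | None = None
    null_sd: float | None = None


def simplified_prioritize(
    individual: str,
    variants: list[AnnotatedVariant],
    genotypes: Mapping[VariantKey, list[GenotypeCall]],
    cfg: FilterConfig,
    gene_sets: GeneSets,
    pedigree: Pedigree | None = None,
    require_configuration: bool = True,
) -> set[str]:
    """Gene set prioritized for one individual under the simplified cascade.

    With ``require_configuration`` the gene must harbor a qualifying
    inheritance configuration (homozygous, >= 2 het candidates not proven in
    cis, male X hemizygote, or confirmed de novo); otherwise any surviving
    variant qualifies the gene.
    """
    simple_cfg = cfg.simplified()
    prioritized, _ = prioritize_patient(
        individual, variants, genotypes, simple_cfg, gene_sets
    )
    by_gene: dict[str, list] = {}
    gt_of: dict[tuple[str, VariantKey], Gt] = {}
    for v in prioritized:
        calls = genotypes.get(v.key, [])
        for c in calls:
            gt_of[(c.sample_id, v.key)] = c.gt
        gt = gt_of.get((individual, v.key))
        if gt is not None and gt.carries_alt():
            by_gene.setdefault(v.gene, []).append((v.key, gt))
    if not require_configuration:
        return set(by_gene)

    def genotype_of(sample: str, key: VariantKey) -> Gt | None:
        return gt_of.get((sample, key))

    out = set()
    for gene, pairs in by_gene.items():
        call = call_gene_inheritance(gene, individual, pairs, pedigree, genotype_of)
        if call is not None:
            out.add(gene)
    return out


def percent_with_prioritized(
    individual_gene_sets: Mapping[str, set[str]], gene_set: set[str]
) -> float:
    """100 x fraction of individuals whose prioritized genes intersect
    ``gene_set`` (unrounded)."""
    if not individual_gene_sets:
        raise MitodxError("empty cohort")
    hits = sum(1 for genes in individual_gene_sets.values() if genes & gene_set)
    return 100.0 * hits / len(individual_gene_sets)


def random_geneset_null(
    individual_gene_sets: Mapping[str, set[str]],
    gene_pool: set[str],
    cfg: EnrichmentConfig,
) -> tuple[float, float, np.ndarray]:
    """Resampling null: percentage of individuals hit by each of ``n_draws``
    random gene sets of size ``random_set_size`` drawn from ``gene_pool``
    (which must already exclude known-disease and mitochondria-related
    genes). Returns (mean, sample SD over draws, draws vector)."""
    pool = sorted(gene_pool)
    if len(pool) < cfg.random_set_size:
        raise MitodxError(
            f"gene pool ({len(pool)}) smaller than random_set_size "
            f"({cfg.random_set_size})"
        )
    rng = np.random.default_rng(cfg.seed)
    draws = np.empty(cfg.n_draws)
    pool_arr = np.array(pool, dtype=object)
    for i in range(cfg.n_draws):
        picked = rng.choice(pool_arr, size=cfg.random_set_size, replace=False)
        draws[i] = percent_with_prioritized(individual_gene_sets, set(picked))
    mean = float(draws.mean())
    sd = float(draws.std(ddof=1)) if cfg.n_draws > 1 else 0.0
    return mean, sd, draws


def enrichment_fold(pct_cases: float, pct_controls: float) -> float | None:
    """Fold enrichment of cases over controls; undefined (None) at 0%
    control background — both percentages are still reported."""
    if pct_controls == 0:
        return None
    return pct_cases / pct_controls


def evaluate_gene_set(
    case_gene_sets: Mapping[str, set[str]],
    control_gene_sets: Mapping[str, set[str]],
    gene_set: set[str],
) -> EnrichmentResult:
    pct_cases = percent_with_prioritized(case_gene_sets, gene_set)
    pct_controls = percent_with_prioritized(control_gene_sets, gene_set)
    return EnrichmentResult(
        pct_cases=pct_cases,
        pct_controls=pct_controls,
        fold=enrichment_fold(pct_cases, pct_controls),
    )


def evaluate_random_null(
    control_gene_sets: Mapping[str, set[str]],
    gene_sets: GeneSets,
    cfg: EnrichmentConfig,
) -> tuple[float, float, np.ndarray]:
    pool = gene_sets.all_genes - gene_sets.known_disease_genes - gene_sets.mito_related_genes
    return random_geneset_null(control_gene_sets, pool, cfg)
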