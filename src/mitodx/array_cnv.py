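"""SNP-array screens: copy-number segmentation and prioritization, long
contiguous stretches of homozygosity (LCSH), cohort Hardy-Weinberg screening,
and composite CNV+SNV compound-heterozygote detection.

Segmentation is a deterministic threshold/run-length caller with explicit
parameters, replacing vendor hidden-Markov software: the prioritization
logic, not the caller, is the scientific content here, and a fully specified
segmenter keeps every boundary exactly reproducible from probe input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import gammaln

from .core import MitodxError

HOM_GENOTYPES = {"AA", "BB"}


@dataclass(frozen=True)
class Probe:
    chrom: str
    pos: int
    genotype: str  # AA | AB | BB | no-call
    log2_ratio: float


@dataclass
class CnvSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    state: str  # deletion | duplication
    n_probes: int
    inheritance: str = "unknown"  # de_novo | paternal | maternal | unknown
    disorder_annotations: list[str] | None = None

    @property
    def size_kb(self) -> float:
        return (self.end - self.start + 1) / 1000.0


@dataclass
class LcshRun:
    chrom: str
    start: int
    end: int
    n_probes: int

    @property
    def length_mb(self) -> float:
        return (self.end - self.start + 1) / 1e6


@dataclass
class HweResult:
    key: str
    n_AA: int
    n_Aa: int
    n_aa: int
    p_value: float
    violated: bool = False


# ---------------------------------------------------------------------------
# copy-number segmentation
# ---------------------------------------------------------------------------

def _check_sorted(probes: Sequence[Probe]) -> None:
    for a, b in zip(probes, probes[1:]):
        if a.chrom == b.chrom and b.pos < a.pos:
            raise MitodxError("probes must be sorted by (chrom, pos)")


def _runs(flags: Sequence[bool], max_gap: int, min_count: int) -> list[tuple[int, int, int]]:
    """Maximal runs of True, tolerating internal gaps of <= max_gap
    consecutive False probes; returns (first_idx, last_idx, n_true)."""
    out = []
    i, n = 0, len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        first = last = i
        count = 1
        j = i + 1
        gap = 0
        while j < n:
            if flags[j]:
                last = j
                count += 1
                gap = 0
            else:
                gap += 1
                if gap > max_gap:
                    break
            j += 1
        if count >= min_count:
            out.append((first, last, count))
        i = last + 1
    return out


def segment_copy_number(
    probes: Sequence[Probe],
    del_thresh: float = -0.3,
    dup_thresh: float = 0.26,
    min_probes: int = 10,
    max_gap: int = 2,
) -> list[CnvSegment]:
    """Call deletion/duplication segments as maximal runs of probes with
    log2 ratios beyond the thresholds. Boundaries are the first and last
    qualifying probe positions."""
    _check_sorted(probes)
    segments: list[CnvSegment] = []
    by_chrom: dict[str, list[Probe]] = {}
    for p in probes:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        for state, flags in (
            ("deletion", [p.log2_ratio <= del_thresh for p in plist]),
            ("duplication", [p.log2_ratio >= dup_thresh for p in plist]),
        ):
            for first, last, count in _runs(flags, max_gap, min_probes):
                segments.append(
                    CnvSegment(chrom, plist[first].pos, plist[last].pos, state, count)
                )
    segments.sort(key=lambda s: (s.chrom, s.start))
    return segments


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    """Min of the two mutual overlap fractions for 1-based inclusive intervals."""
    inter = min(a_end, b_end) - max(a_start, b_start) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start + 1), inter / (b_end - b_start + 1))


def prioritize_cnv(
    segments: Iterable[CnvSegment],
    control_cnvs: Mapping[str, IntervalTree],
    disorder_regions: Mapping[str, IntervalTree],
    min_kb: float = 100.0,
    max_control_overlap: float = 0.5,
) -> list[CnvSegment]:
    """Keep segments strictly larger than ``min_kb`` whose reciprocal overlap
    with every control-cohort CNV stays below ``max_control_overlap``;
    annotate survivors with overlapping known genomic-disorder regions.

    Control/disorder trees use BED coordinates (0-based half-open)."""
    kept = []
    for seg in segments:
        if seg.size_kb <= min_kb:
            continue
        tree = control_cnvs.get(seg.chrom)
        in_controls = False
        if tree is not None:
            for iv in tree.overlap(seg.start - 1, seg.end):
                if reciprocal_overlap(seg.start, seg.end, iv.begin + 1, iv.end) >= max_control_overlap:
                    in_controls = True
                    break
        if in_controls:
            continue
        annotations = []
        dtree = disorder_regions.get(seg.chrom)
        if dtree is not None:
            annotations = sorted(
                iv.data for iv in dtree.overlap(seg.start - 1, seg.end) if iv.data
            )
        seg.disorder_annotations = annotations
        kept.append(seg)
    return kept


# ---------------------------------------------------------------------------
# LCSH
# ---------------------------------------------------------------------------

def detect_lcsh(
    probes: Sequence[Probe], min_mb: float = 1.0, max_het_interrupt: int = 0
) -> list[LcshRun]:
    """Maximal runs of homozygous genotype calls spanning >= ``min_mb``.

    No-call probes are ignored; up to ``max_het_interrupt`` isolated
    heterozygous calls are tolerated inside a run (greedy left-to-right
    extension; exact maximality holds at the default of 0)."""
    _check_sorted(probes)
    runs: list[LcshRun] = []
    by_chrom: dict[str, list[Probe]] = {}
    for p in probes:
        if p.genotype == "no-call":
            continue
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        flags = [p.genotype in HOM_GENOTYPES for p in plist]
        for first, last, count in _runs(flags, max_het_interrupt, 1):
            run = LcshRun(chrom, plist[first].pos, plist[last].pos, count)
            if run.length_mb >= min_mb:
                runs.append(run)
    runs.sort(key=lambda r: (r.chrom, r.start))
    return runs


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact screening
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Two-sided p-value: the probability, under the exact conditional
    distribution of the heterozygote count given the allele counts, of all
    outcomes no more probable than the observed one. Monomorphic sites give
    p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise MitodxError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0

    # enumerate heterozygote counts with the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_common = max(n_a, n_A)
    hom_rare = (rare - hets) // 2
    hom_common = (n_common - hets) // 2
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(n_a + 1)
        + gammaln(n_A + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    obs = np.searchsorted(hets, n_Aa)
    if obs >= len(hets) or hets[obs] != n_Aa:
        raise MitodxError("observed heterozygote count inconsistent with allele counts")
    p = float(probs[probs <= probs[obs] * (1.0 + 1e-12)].sum())
    return min(1.0, p)


def hwe_screen(
    counts: Mapping[str, tuple[int, int, int]], alpha: float = 0.05
) -> list[HweResult]:
    """Exact HWE test per variant with Bonferroni adjustment across the
    screened variants; ``violated`` marks adjusted significance."""
    m = len(counts)
    results = []
    for key, (n_AA, n_Aa, n_aa) in counts.items():
        p = hwe_exact_test(n_AA, n_Aa, n_aa)
        results.append(HweResult(key, n_AA, n_Aa, n_aa, p, violated=(p * m) < alpha))
    return results


# ---------------------------------------------------------------------------
# composite CNV + SNV findings
# ---------------------------------------------------------------------------

@dataclass
class CompositeFinding:
    gene: str
    segment: CnvSegment
    variant_key: str
    variant_gt: str
    note: str = ""


def detect_composite_cnv_snv(
    segments: Iterable[CnvSegment],
    gene_regions: Mapping[str, tuple[str, int, int]],
    prioritized_gene_variants: Mapping[str, list[tuple[str, str]]],
) -> list[CompositeFinding]:
    """Promote het variants under het deletions to biallelic candidates.

    ``gene_regions`` maps gene -> (chrom, start, end) 1-based inclusive;
    ``prioritized_gene_variants`` maps gene -> [(variant key string, gt)] for
    one patient. A heterozygous variant inside a heterozygous deletion means
    both copies are hit (deletion in trans with the SNV); an apparently
    homozygous variant under a het deletion is really hemizygous and is
    reported with a note rather than dropped.
    """
    out = []
    for seg in segments:
        if seg.state != "deletion":
            continue
        for gene, (chrom, gstart, gend) in gene_regions.items():
            if chrom != seg.chrom or gend < seg.start or gstart > seg.end:
                continue
            for key, gt in prioritized_gene_variants.get(gene, []):
                if gt == "het":
                    out.append(CompositeFinding(gene, seg, key, gt))
                elif gt == "hom_alt":
                    out.append(
                        CompositeFinding(
                            gene, seg, key, gt,
                            note="apparent homozygote under het deletion: "
                                 "hemizygous variant (one allele deleted)",
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# probe table IO
# ---------------------------------------------------------------------------

def read_probe_table(path: str | Path) -> dict[str, list[Probe]]:
    """Per-sample probes from a table with columns
    sample, chrom, pos, genotype, log2_ratio (sorted within sample)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str, "genotype": str})
    out: dict[str, list[Probe]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample, []).append(
            Probe(row.chrom, int(row.pos), row.genotype, float(row.log2_ratio))
        )
    for plist in out.values():
        _check_sorted(plist)
    return out
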