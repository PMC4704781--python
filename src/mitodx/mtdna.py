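"""mtDNA analysis: heteroplasmy calls, catalog-based prioritization,
circular-genome large-deletion detection, and the mtDNA-depletion (MTDPS) rule.

All positions are 1-based on the 16,569-bp circular revised Cambridge
Reference Sequence (rCRS). Deletion spans are inclusive, traversed in the
direction of increasing position with wrap-around through the origin, so
``deletion_length(16560, 10)`` is 20 bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import MitodxError

RCRS_LENGTH = 16569


@dataclass(frozen=True)
class MtVariant:
    pos: int
    ref: str
    alt: str
    heteroplasmy: float
    catalog_status: str = "absent"  # confirmed | reported | absent

    def __post_init__(self) -> None:
        if not (0.0 <= self.heteroplasmy <= 1.0):
            raise ValueError("heteroplasmy must be in [0,1]")


@dataclass
class CoverageProfile:
    """Per-base read depth over the circular mitochondrial genome."""

    depth: np.ndarray  # length RCRS_LENGTH (or toy length), index 0 = position 1
    circular: bool = True

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValueError("depths must be non-negative")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass(frozen=True)
class MtDeletion:
    first_deleted: int
    last_deleted: int
    length: int
    heteroplasmy: float | None = None  # 1 - arc depth / flanking depth


@dataclass(frozen=True)
class DepletionRule:
    """Diagnose MTDPS when every replicate mtDNA/nuclear copy ratio is below
    ``ratio_threshold`` of the healthy-control ratio, across ``n_experiments``
    independent experiments."""

    ratio_threshold: float = 0.35
    n_experiments: int = 4

    def __post_init__(self) -> None:
        if not (0.0 < self.ratio_threshold < 1.0):
            raise ValueError("ratio_threshold must be in (0,1)")


def deletion_length(first_deleted: int, last_deleted: int, genome_len: int = RCRS_LENGTH) -> int:
    """Inclusive span of a (possibly origin-wrapping) circular deletion."""
    for pos in (first_deleted, last_deleted):
        if not (1 <= pos <= genome_len):
            raise ValueError(f"position {pos} outside 1..{genome_len}")
    if last_deleted >= first_deleted:
        return last_deleted - first_deleted + 1
    return genome_len - first_deleted + 1 + last_deleted


def circular_positions(start: int, end: int, genome_len: int = RCRS_LENGTH) -> np.ndarray:
    """1-based positions of the inclusive circular arc start..end."""
    n = deletion_length(start, end, genome_len)
    return (np.arange(start - 1, start - 1 + n) % genome_len) + 1


def call_heteroplasmy(ref_count: int, alt_count: int, min_depth: int = 20) -> float | None:
    """Alt-allele fraction, or None (no-call) below the depth gate."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total < min_depth:
        return None
    return alt_count / total


def read_mt_catalog(path: str | Path) -> dict[tuple[int, str, str], str]:
    """Tab-delimited pathogenicity catalog: pos, ref, alt, status."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str, "status": str})
    out = {}
    for row in df.itertuples(index=False):
        status = row.status.strip().lower()
        if status not in ("confirmed", "reported"):
            raise MitodxError(f"unknown catalog status {row.status!r}")
        out[(int(row.pos), row.ref, row.alt)] = status
    return out


def prioritize_mt_variants(
    variants: Iterable[MtVariant], catalog: dict[tuple[int, str, str], str]
) -> list[MtVariant]:
    """Retain variants present in the pathogenicity catalog, annotated with
    catalog status. Confirmed entries are firm-eligible; reported-but-
    unconfirmed entries are pVUS-eligible (the classifier decides)."""
    out = []
    for v in variants:
        status = catalog.get((v.pos, v.ref, v.alt))
        if status is not None:
            out.append(MtVariant(v.pos, v.ref, v.alt, v.heteroplasmy, status))
    return out


def read_mt_variant_table(path: str | Path, min_depth: int = 20) -> dict[str, list[MtVariant]]:
    """Per-sample mtDNA variants from a table with columns
    sample, pos, ref, alt, ref_count, alt_count."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "ref": str, "alt": str})
    out: dict[str, list[MtVariant]] = {}
    for row in df.itertuples(index=False):
        frac = call_heteroplasmy(int(row.ref_count), int(row.alt_count), min_depth)
        if frac is None:
            continue
        out.setdefault(row.sample, []).append(
            MtVariant(int(row.pos), row.ref, row.alt, frac)
        )
    return out


def detect_large_deletion(
    profile: CoverageProfile, drop_factor: float = 0.5, min_span: int = 100
) -> MtDeletion | None:
    """Find the maximal circular low-coverage arc consistent with a single
    large deletion.

    A base is "low" when its depth falls below ``drop_factor`` times a
    robust reference level (the upper-quartile depth, so that deletions
    covering up to ~75% of the circle do not drag the reference down). The
    maximal circular run of low bases is a deletion when it spans at least
    ``min_span`` bases and its mean depth is below ``drop_factor`` times the
    flanking (non-arc) mean. Breakpoints are the first and last low bases of
    the arc.
    """
    depth = profile.depth
    n = len(depth)
    reference = float(np.percentile(depth, 75))
    if reference <= 0:
        raise MitodxError("whole-genome coverage is zero: no reference level")
    low = depth < drop_factor * reference
    if low.all():
        raise MitodxError("entire genome is low-coverage: no reference level")
    if not low.any():
        return None

    # longest run of True on a circle: unroll at a False position
    anchor = int(np.argmin(low))  # index of some False
    order = (np.arange(n) + anchor) % n
    rolled = low[order]
    best_len, best_start = 0, None
    run_len = 0
    for i, flag in enumerate(rolled):
        if flag:
            run_len += 1
            if run_len > best_len:
                best_len = run_len
                best_start = i - run_len + 1
        else:
            run_len = 0
    assert best_start is not None
    first_idx = int(order[best_start])
    last_idx = int(order[best_start + best_len - 1])
    first, last = first_idx + 1, last_idx + 1
    span = deletion_length(first, last, n)
    if span < min_span:
        return None
    arc = (circular_positions(first, last, n) - 1).astype(int)
    mask = np.zeros(n, dtype=bool)
    mask[arc] = True
    arc_mean = float(depth[mask].mean())
    flank_mean = float(depth[~mask].mean())
    if flank_mean <= 0 or arc_mean >= drop_factor * flank_mean:
        return None
    return MtDeletion(
        first_deleted=first,
        last_deleted=last,
        length=span,
        heteroplasmy=max(0.0, 1.0 - arc_mean / flank_mean),
    )


def read_coverage_table(path: str | Path) -> dict[str, CoverageProfile]:
    """Per-sample coverage from a table with columns sample, pos, depth."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    out = {}
    for sample, grp in df.groupby("sample", sort=False):
        grp = grp.sort_values("pos")
        positions = grp["pos"].to_numpy()
        if positions[0] != 1 or positions[-1] != len(positions):
            raise MitodxError(f"coverage for {sample} is not a dense 1..L profile")
        out[str(sample)] = CoverageProfile(grp["depth"].to_numpy())
    return out


def call_depletion(
    patient_ratios: Sequence[float],
    control_mean: float,
    rule: DepletionRule = DepletionRule(),
) -> str:
    """MTDPS iff *every* replicate ratio is < threshold × control mean."""
    if len(patient_ratios) != rule.n_experiments:
        raise MitodxError(
            f"depletion rule requires exactly {rule.n_experiments} replicate "
            f"ratios, got {len(patient_ratios)}"
        )
    if control_mean <= 0:
        raise ValueError("control_mean must be positive")
    if all(r / control_mean < rule.ratio_threshold for r in patient_ratios):
        return "MTDPS"
    return "normal"


def read_qpcr_table(path: str | Path) -> dict[str, tuple[list[float], float]]:
    """qPCR copy-ratio table: sample, tissue, rep1..rep4, control_mean."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    out = {}
    for row in df.itertuples(index=False):
        ratios = [float(row.rep1), float(row.rep2), float(row.rep3), float(row.rep4)]
        out[row.sample] = (ratios, float(row.control_mean))
    return out
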