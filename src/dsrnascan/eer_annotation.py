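"""Editing-enriched regions (EERs) and the structure-verified positive set.

ADAR edits adenosines within double-stranded RNA, so clusters of known
A-to-I sites mark duplex-forming loci. Dense site clusters (>= 3 sites
within any 50-nt span) are called editing-enriched, nearby regions are
merged, and each merged region is folded; only regions that fold into a
long near-perfect duplex are kept as curated dsRNAs. These curated regions
are the positive labels for classifier training and are excluded from novel
discovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .alignment_io import EditingSite, GenomicInterval
from .feature_extraction import chromosome_length, fetch_sequence
from .structure_curation import (
    DEFAULT_AMFE_THRESHOLD,
    DEFAULT_MAX_FOLD_LENGTH,
    DEFAULT_MAX_MISMATCH,
    DEFAULT_MIN_STEM,
    FoldResult,
    StemReport,
    fold_sequence,
    stem_report,
)

logger = logging.getLogger(__name__)

DEFAULT_EER_SPAN = 50
DEFAULT_EER_MIN_SITES = 3
DEFAULT_MERGE_GAP = 1000
#: Regions shorter than this are padded symmetrically before folding so a
#: >= 200-bp stem is representable at all.
DEFAULT_FOLD_PAD = 200


@dataclass(frozen=True)
class EERInterval:
    """An editing-enriched genomic interval."""

    interval: GenomicInterval
    n_sites: int

    def __post_init__(self) -> None:
        if self.n_sites < DEFAULT_EER_MIN_SITES:
            raise ValueError("an EER holds at least three editing sites")


@dataclass(frozen=True)
class CuratedDsRNA:
    """A structure-verified positive dsRNA region."""

    interval: GenomicInterval
    fold: FoldResult
    stem: StemReport


def find_editing_enriched(
    sites: Sequence[EditingSite],
    span: int = DEFAULT_EER_SPAN,
    min_sites: int = DEFAULT_EER_MIN_SITES,
) -> list[EERInterval]:
    """Scan a sorted site catalog for editing-enriched intervals.

    Any ``min_sites`` consecutive sites whose positions fit strictly within a
    ``span``-nt window (max - min < span) seed the enriched interval
    ``[first.pos, last.pos + 1)``; overlapping or abutting seeds are unioned
    and site counts re-tallied on the union. Sites on both strands are
    pooled.
    """
    by_chrom: dict[str, list[int]] = {}
    for site in sites:
        by_chrom.setdefault(site.chrom, []).append(site.pos)
    out: list[EERInterval] = []
    for chrom in sorted(by_chrom):
        positions = sorted(set(by_chrom[chrom]))
        seeds: list[tuple[int, int]] = []
        for i in range(len(positions) - min_sites + 1):
            lo = positions[i]
            hi = positions[i + min_sites - 1]
            if hi - lo < span:
                seeds.append((lo, hi + 1))
        for start, end in _union(seeds):
            n = sum(start <= p < end for p in positions)
            out.append(EERInterval(GenomicInterval(chrom, start, end), n))
    return out


def _union(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping or abutting (start, end) pairs."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def merge_nearby(
    intervals: Iterable[GenomicInterval], gap: int = DEFAULT_MERGE_GAP
) -> list[GenomicInterval]:
    """Merge same-chromosome intervals whose separation is <= ``gap`` nt.

    Separation is ``next.start - prev.end`` (0 when abutting or overlapping).
    Idempotent; output sorted with pairwise separation > ``gap``.
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= gap
        ):
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end)
            )
        else:
            merged.append(iv)
    return merged


def curate_positive_regions(
    merged: Iterable[GenomicInterval],
    reference,
    min_stem: int = DEFAULT_MIN_STEM,
    max_mismatch: float = DEFAULT_MAX_MISMATCH,
    amfe_threshold: float = DEFAULT_AMFE_THRESHOLD,
    max_fold_length: int = DEFAULT_MAX_FOLD_LENGTH,
    fold_pad: int = DEFAULT_FOLD_PAD,
    fold: Callable[..., FoldResult] = fold_sequence,
) -> list[CuratedDsRNA]:
    """Structure-verify merged EERs; keep those folding into a long duplex.

    Intervals shorter than ``fold_pad`` nt are padded symmetrically (clipped
    at chromosome bounds) before folding so the stem criterion is decidable.
    Intervals exceeding the folding length limit are skipped with a log
    message rather than crashing the curation run.
    """
    curated: list[CuratedDsRNA] = []
    for iv in merged:
        chrom_len = chromosome_length(reference, iv.chrom)
        start, end = iv.start, iv.end
        if end - start < fold_pad:
            pad = fold_pad - (end - start)
            start = max(0, start - pad // 2)
            end = min(chrom_len, start + fold_pad)
            start = max(0, end - fold_pad)
        padded = GenomicInterval(iv.chrom, start, end)
        if padded.length > max_fold_length:
            logger.info(
                "skipping %s:%d-%d: %d nt exceeds folding limit %d",
                padded.chrom, padded.start, padded.end, padded.length, max_fold_length,
            )
            continue
        seq = fetch_sequence(reference, padded.chrom, padded.start, padded.end)
        result = fold(seq)
        stem = stem_report(result.dotbracket)
        if stem.length < min_stem:
            logger.info("dropping %s: stem %d < %d", padded, stem.length, min_stem)
            continue
        if stem.span_mismatch_fraction > max_mismatch:
            logger.info(
                "dropping %s: mismatch %.3f > %.3f",
                padded, stem.span_mismatch_fraction, max_mismatch,
            )
            continue
        if result.amfe > amfe_threshold:
            logger.info(
                "dropping %s: AMFE %.2f > %.2f", padded, result.amfe, amfe_threshold
            )
            continue
        curated.append(CuratedDsRNA(interval=padded, fold=result, stem=stem))
    return curated


def write_bed(intervals: Iterable[GenomicInterval], path: str, name: str = "EER") -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t.\n")


def write_curated_table(curated: Sequence[CuratedDsRNA], path: str) -> None:
    """TSV of fold metrics for each curated positive region."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmfe\tamfe\tstem_length\tmismatch_fraction\n")
        for c in curated:
            fh.write(
                f"{c.interval.chrom}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.fold.mfe:.2f}\t{c.fold.amfe:.4f}\t{c.stem.length}\t"
                f"{c.stem.span_mismatch_fraction:.4f}\n"
            )
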