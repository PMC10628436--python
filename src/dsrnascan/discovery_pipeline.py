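"""Genome-wide discovery of novel dsRNA regions.

The scan tiles every chromosome with 2500-nt windows at a 1250-nt stride,
keeps windows with >= 6 overlapping reads and >= 1 internally skipping read,
scores them with a trained forest, drops windows at or below 0.5 probability
or overlapping any curated (editing-derived) positive region, folds the
survivors and splits them into novel long dsRNAs versus generally structured
RNAs. A pooled per-region A-to-I editing index (G / (A+G) over catalog sites
covered by more than three reads) annotates how edited each region is.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import pandas as pd
import pysam

from .alignment_io import (
    DEFAULT_MIN_SKIP_LENGTH,
    AlignedRead,
    EditingSite,
    GenomicInterval,
    index_reads_by_window,
)
from .classifier import DEFAULT_MIN_READS, DEFAULT_WINDOW_SIZE, TrainedModel, predict_proba
from .feature_extraction import (
    FEATURE_NAMES,
    FeatureVector,
    extract_features,
    fetch_sequence,
)
from .structure_curation import (
    FoldResult,
    StemReport,
    StructureClass,
    classify_structure,
    fold_sequence,
    stem_report,
)

logger = logging.getLogger(__name__)

DEFAULT_STEP = 1250
DEFAULT_PROBABILITY_THRESHOLD = 0.5
#: A site qualifies for the editing index when covered by at least this many
#: aligned (non-deleted) read bases, i.e. by more than three reads.
DEFAULT_MIN_SITE_COVERAGE = 4


@dataclass
class CandidateWindow:
    """A read-supported window awaiting (or carrying) a model score."""

    interval: GenomicInterval
    features: FeatureVector
    probability: float | None = None


@dataclass
class DiscoveredRegion:
    interval: GenomicInterval
    probability: float
    structure_class: StructureClass
    fold: FoldResult
    stem: StemReport
    editing_index: float | None = None


@dataclass(frozen=True)
class EditingIndexResult:
    region: GenomicInterval
    g_count: int
    a_count: int
    n_sites_used: int

    @property
    def index(self) -> float | None:
        total = self.a_count + self.g_count
        if total == 0:
            return None
        return self.g_count / total


def window_starts(chrom_length: int, window: int, step: int) -> list[int]:
    """Tiling starts: stride ``step``; a trailing partial window is kept only
    when strictly longer than one stride (otherwise it covers no new base)."""
    starts = []
    pos = 0
    while pos < chrom_length:
        length = min(pos + window, chrom_length) - pos
        if length == window or length > step:
            starts.append(pos)
        pos += step
    return starts


def enumerate_candidate_windows(
    reference,
    reads: Sequence[AlignedRead],
    window: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
    min_reads: int = DEFAULT_MIN_READS,
    min_skip_length: int = DEFAULT_MIN_SKIP_LENGTH,
) -> list[CandidateWindow]:
    """Tile the genome and keep windows passing the read-support filter."""
    from .feature_extraction import chromosome_length, chromosome_names

    reads_by_chrom: dict[str, list[AlignedRead]] = {}
    for r in reads:
        reads_by_chrom.setdefault(r.chrom, []).append(r)
    candidates: list[CandidateWindow] = []
    for chrom in chromosome_names(reference):
        chrom_reads = reads_by_chrom.get(chrom, [])
        if not chrom_reads:
            continue
        chrom_len = chromosome_length(reference, chrom)
        for start in window_starts(chrom_len, window, step):
            iv = GenomicInterval(chrom, start, min(start + window, chrom_len))
            idx = index_reads_by_window(chrom_reads, iv, min_skip_length=min_skip_length)
            if idx.total_reads < min_reads or idx.skipping_reads < 1:
                continue
            fv = extract_features(
                iv, chrom_reads, reference, min_skip_length=min_skip_length
            )
            candidates.append(CandidateWindow(interval=iv, features=fv))
    return candidates


def discover_dsrna(
    candidates: Sequence[CandidateWindow],
    model: TrainedModel,
    positives: Iterable[GenomicInterval],
    reference,
    probability_threshold: float = DEFAULT_PROBABILITY_THRESHOLD,
    fold: Callable[[str], FoldResult] = fold_sequence,
) -> list[DiscoveredRegion]:
    """Score candidates and structure-classify the confident, non-EER ones.

    Retains windows with probability strictly above the threshold, drops any
    overlapping (>= 1 nt) a curated positive region, folds the rest and
    labels them novel long dsRNA or structured RNA. A folding failure skips
    that window with a log message. Output is sorted by probability
    descending (ties by coordinate).
    """
    if not candidates:
        return []
    positives = list(positives)
    frame = pd.DataFrame(
        [c.features.to_series() for c in candidates], columns=list(FEATURE_NAMES)
    )
    probabilities = predict_proba(model, frame)
    discovered: list[DiscoveredRegion] = []
    for cand, prob in zip(candidates, probabilities):
        cand.probability = float(prob)
        if prob <= probability_threshold:
            continue
        if any(cand.interval.overlaps(p) for p in positives):
            continue
        seq = fetch_sequence(
            reference, cand.interval.chrom, cand.interval.start, cand.interval.end
        )
        try:
            fold_result = fold(seq)
        except (ValueError, RuntimeError) as exc:
            logger.warning("folding failed for %s: %s", cand.interval, exc)
            continue
        stem = stem_report(fold_result.dotbracket)
        discovered.append(
            DiscoveredRegion(
                interval=cand.interval,
                probability=float(prob),
                structure_class=classify_structure(fold_result, stem),
                fold=fold_result,
                stem=stem,
            )
        )
    discovered.sort(key=lambda r: (-r.probability, r.interval))
    return discovered


# --- editing index ------------------------------------------------------------------


def compute_editing_index(
    region: GenomicInterval,
    alignments,
    sites: Sequence[EditingSite],
    min_coverage: int = DEFAULT_MIN_SITE_COVERAGE,
) -> EditingIndexResult:
    """Pooled editing index over catalog sites inside a region.

    ``alignments`` is an indexed ``pysam.AlignmentFile`` (or a path to one).
    Coverage of a site counts aligned, non-deleted read bases at that
    position; sites below ``min_coverage`` are excluded. On the + strand,
    reference-A positions read as G are edited; on the - strand the
    sequenced complement is counted (T positions read as C). Reads are not
    strand-filtered. The index is undefined (None) without qualifying
    A/G observations.
    """
    close = False
    if isinstance(alignments, str):
        mode = "rb" if alignments.endswith(".bam") else "r"
        alignments = pysam.AlignmentFile(alignments, mode)
        close = True
    try:
        region_sites = [s for s in sites if region.contains(s.chrom, s.pos)]
        bases_per_site: dict[int, list[str]] = {s.pos: [] for s in region_sites}
        if region_sites:
            for rec in alignments.fetch(region.chrom, region.start, region.end):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                seq = rec.query_sequence
                if seq is None:
                    continue
                for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
                    if rpos in bases_per_site:
                        bases_per_site[rpos].append(seq[qpos].upper())
        a_total = 0
        g_total = 0
        used = 0
        for site in region_sites:
            bases = bases_per_site[site.pos]
            if len(bases) < min_coverage:
                continue
            used += 1
            if site.strand == "+":
                a_total += sum(b == "A" for b in bases)
                g_total += sum(b == "G" for b in bases)
            else:
                a_total += sum(b == "T" for b in bases)
                g_total += sum(b == "C" for b in bases)
        return EditingIndexResult(region, g_count=g_total, a_count=a_total, n_sites_used=used)
    finally:
        if close:
            alignments.close()


# --- export -------------------------------------------------------------------------


def export_results(
    regions: Sequence[DiscoveredRegion], bed_path: str, tsv_path: str
) -> None:
    """Write discoveries as BED6 (name = class, score = round(prob * 1000))
    and a full-metric TSV. Byte-deterministic for fixed input."""
    with open(bed_path, "w") as bed:
        for r in regions:
            bed.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.structure_class.value}\t{round(r.probability * 1000)}\t.\n"
            )
    with open(tsv_path, "w") as tsv:
        tsv.write(
            "chrom\tstart\tend\tprobability\tclass\tmfe\tamfe\t"
            "stem_length\tmismatch_fraction\tediting_index\n"
        )
        for r in regions:
            idx = "NA" if r.editing_index is None else f"{r.editing_index:.4f}"
            tsv.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.probability:.6f}\t{r.structure_class.value}\t{r.fold.mfe:.2f}\t"
                f"{r.fold.amfe:.4f}\t{r.stem.length}\t"
                f"{r.stem.span_mismatch_fraction:.4f}\t{idx}\n"
            )
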