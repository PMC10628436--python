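"""Per-window predictor features for the dsRNA random-forest classifier.

Template-switching skips and spliced introns leave different footprints in a
window of aligned reads. Splicing is frequent among the reads of a locus,
lands on exact GT..AG junctions and repeats at identical coordinates;
template switching over a hairpin is rare per molecule, motif-free and its
boundaries jitter from read to read. The 38 features computed here encode
exactly that contrast:

* ``skip_ratio`` — fraction of window reads carrying an internal skip;
* ``len_skip`` — mean skipped length (nt) over skip events;
* ``group_num`` — number of skip-boundary clusters (mean of start- and
  end-side counts, possibly half-integer);
* ``std_start``/``std_end`` — mean within-cluster population standard
  deviation of boundary coordinates (nt);
* ``gc_skip`` — mean GC fraction of the skipped reference segments;
* ``bp_start_XY``/``bp_end_XY`` — frequency of each of the 16 dinucleotides
  as the first two / last two reference bases of the skipped segment
  (GT / AG for true introns).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment_io import (
    DEFAULT_MIN_SKIP_LENGTH,
    AlignedRead,
    GenomicInterval,
    SkipEvent,
    index_reads_by_window,
)

DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in "ACGT" for b in "ACGT")

FEATURE_NAMES: tuple[str, ...] = (
    "skip_ratio",
    "len_skip",
    "group_num",
    "std_start",
    "std_end",
    "gc_skip",
    *(f"bp_start_{d}" for d in DINUCLEOTIDES),
    *(f"bp_end_{d}" for d in DINUCLEOTIDES),
)

DEFAULT_GROUP_RADIUS = 100


@dataclass(frozen=True)
class SkipGroup:
    """One cluster of skip boundary coordinates (all starts, or all ends)."""

    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("a skip group cannot be empty")

    @property
    def median(self) -> float:
        return float(np.median(self.positions))

    @property
    def spread(self) -> float:
        """Population standard deviation (divisor n; 0 for singletons)."""
        return float(np.std(self.positions))


@dataclass(frozen=True)
class FeatureVector:
    """The 38 per-window predictors, in canonical :data:`FEATURE_NAMES` order."""

    skip_ratio: float
    len_skip: float
    group_num: float
    std_start: float
    std_end: float
    gc_skip: float
    bp_start: Mapping[str, float]
    bp_end: Mapping[str, float]

    def __post_init__(self) -> None:
        for side, freqs in (("bp_start", self.bp_start), ("bp_end", self.bp_end)):
            if set(freqs) != set(DINUCLEOTIDES):
                raise ValueError(f"{side} must hold all 16 dinucleotide frequencies")
            total = sum(freqs.values())
            if total > 1.0 + 1e-9 or any(v < 0 for v in freqs.values()):
                raise ValueError(f"{side} frequencies must be non-negative, sum <= 1")

    def to_series(self) -> pd.Series:
        values = [
            self.skip_ratio,
            self.len_skip,
            self.group_num,
            self.std_start,
            self.std_end,
            self.gc_skip,
            *(self.bp_start[d] for d in DINUCLEOTIDES),
            *(self.bp_end[d] for d in DINUCLEOTIDES),
        ]
        return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def compute_skip_stats(
    total_reads: int, skips: Sequence[SkipEvent], skipping_reads: int
) -> tuple[float, float]:
    """Skipping ratio and mean skipped length of a window."""
    if total_reads == 0:
        raise ValueError("empty window reached feature stage")
    if skipping_reads == 0 or not skips:
        raise ValueError("window without skipping reads reached feature stage")
    skip_ratio = skipping_reads / total_reads
    len_skip = float(np.mean([sk.length for sk in skips]))
    return skip_ratio, len_skip


# --- boundary clustering ------------------------------------------------------------


def _group_ok(positions: Sequence[int], lo: int, hi: int, radius: int) -> bool:
    """Is ``positions[lo:hi]`` an admissible group?

    Admissible means consecutive members lie within ``radius`` of each other
    and both extremes are strictly within ``radius`` of the group median.
    """
    seg = positions[lo:hi]
    for a, b in zip(seg, seg[1:]):
        if b - a > radius:
            return False
    med = statistics.median(seg)
    return (seg[-1] - med) < radius and (med - seg[0]) < radius


def group_positions(
    positions: Iterable[int], radius: int = DEFAULT_GROUP_RADIUS
) -> list[SkipGroup]:
    """Partition boundary coordinates into the coarsest admissible clustering.

    Among all contiguous partitions of the sorted coordinates whose every
    group is admissible (see :func:`_group_ok`), the one with the fewest
    groups is returned; ties are broken by greedily making each group, left
    to right, as long as the remaining minimum allows. Singletons are always
    admissible, so a solution exists. Deterministic and invariant to input
    order.
    """
    pos = sorted(positions)
    if not pos:
        raise ValueError("cannot group an empty list of positions")
    n = len(pos)
    inf = n + 1
    # best[i] = minimal number of groups partitioning pos[i:]
    best = [inf] * (n + 1)
    best[n] = 0
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n + 1):
            # extremes within radius of the median bounds the span below 2*radius
            if pos[j - 1] - pos[i] >= 2 * radius:
                break
            if _group_ok(pos, i, j, radius) and 1 + best[j] < best[i]:
                best[i] = 1 + best[j]
    groups: list[SkipGroup] = []
    i = 0
    while i < n:
        chosen = None
        for j in range(i + 1, n + 1):
            if pos[j - 1] - pos[i] >= 2 * radius:
                break
            if _group_ok(pos, i, j, radius) and 1 + best[j] == best[i]:
                chosen = j  # keep extending: prefer the longest admissible group
        assert chosen is not None
        groups.append(SkipGroup(tuple(pos[i:chosen])))
        i = chosen
    return groups


def group_summary(
    start_groups: Sequence[SkipGroup], end_groups: Sequence[SkipGroup]
) -> tuple[float, float, float]:
    """Aggregate cluster counts and within-cluster spreads over both sides.

    The group count is the mean of the start-side and end-side counts (a
    half-integer when they differ); each side's spread is the mean of its
    per-group population standard deviations.
    """
    if not start_groups or not end_groups:
        raise ValueError("group summaries require non-empty group lists")
    group_num = (len(start_groups) + len(end_groups)) / 2
    std_start = float(np.mean([g.spread for g in start_groups]))
    std_end = float(np.mean([g.spread for g in end_groups]))
    return group_num, std_start, std_end


# --- reference sequence access ------------------------------------------------------


def fetch_sequence(reference, chrom: str, start: int, end: int) -> str:
    """Uppercase reference bases for ``chrom[start:end)``.

    Accepts a plain mapping of chromosome to sequence string, a
    ``pyfaidx.Fasta``, or a ``pysam.FastaFile``.
    """
    if hasattr(reference, "fetch"):  # pysam.FastaFile
        try:
            return reference.fetch(chrom, start, end).upper()
        except KeyError:
            raise KeyError(f"reference chromosome {chrom!r} missing") from None
    try:
        record = reference[chrom]
    except KeyError:
        raise KeyError(f"reference chromosome {chrom!r} missing") from None
    seq = record[start:end]
    return str(seq).upper()


def chromosome_length(reference, chrom: str) -> int:
    if hasattr(reference, "get_reference_length"):  # pysam.FastaFile
        return reference.get_reference_length(chrom)
    try:
        return len(reference[chrom])
    except KeyError:
        raise KeyError(f"reference chromosome {chrom!r} missing") from None


def chromosome_names(reference) -> list[str]:
    if hasattr(reference, "references"):  # pysam.FastaFile
        return list(reference.references)
    return list(reference.keys())


# --- skipped-segment composition ----------------------------------------------------


def skipped_segment_composition(
    skips: Sequence[SkipEvent], reference
) -> tuple[float, dict[str, float], dict[str, float]]:
    """GC content of skipped segments and their boundary dinucleotide spectra.

    All composition is read off the reference: the skipped bases are, by
    definition, absent from the read itself. The start dinucleotide is the
    first two bases of the skipped segment, the end dinucleotide the last
    two (GT..AG for genuine introns). Events whose boundary dinucleotide
    contains an ambiguous base are dropped from that side's denominator.
    """
    if not skips:
        raise ValueError("composition requires at least one skip event")
    gc_fracs: list[float] = []
    start_counts = {d: 0 for d in DINUCLEOTIDES}
    end_counts = {d: 0 for d in DINUCLEOTIDES}
    n_start = 0
    n_end = 0
    for sk in skips:
        if sk.length < 2:
            raise ValueError("skip shorter than 2 nt has no boundary dinucleotides")
        seq = fetch_sequence(reference, sk.chrom, sk.start, sk.end)
        acgt = [b for b in seq if b in "ACGT"]
        if acgt:
            gc_fracs.append(sum(b in "GC" for b in acgt) / len(acgt))
        else:
            gc_fracs.append(0.0)
        start_dn = seq[:2]
        end_dn = seq[-2:]
        if start_dn in start_counts:
            start_counts[start_dn] += 1
            n_start += 1
        if end_dn in end_counts:
            end_counts[end_dn] += 1
            n_end += 1
    gc_skip = float(np.mean(gc_fracs))
    bp_start = {d: (c / n_start if n_start else 0.0) for d, c in start_counts.items()}
    bp_end = {d: (c / n_end if n_end else 0.0) for d, c in end_counts.items()}
    return gc_skip, bp_start, bp_end


def extract_features(
    window: GenomicInterval,
    reads: Iterable[AlignedRead],
    reference,
    min_skip_length: int = DEFAULT_MIN_SKIP_LENGTH,
    group_radius: int = DEFAULT_GROUP_RADIUS,
) -> FeatureVector:
    """Assemble the full 38-field feature vector for one candidate window."""
    idx = index_reads_by_window(reads, window, min_skip_length=min_skip_length)
    skip_ratio, len_skip = compute_skip_stats(idx.total_reads, idx.skips, idx.skipping_reads)
    start_groups = group_positions([sk.start for sk in idx.skips], radius=group_radius)
    end_groups = group_positions([sk.end for sk in idx.skips], radius=group_radius)
    group_num, std_start, std_end = group_summary(start_groups, end_groups)
    gc_skip, bp_start, bp_end = skipped_segment_composition(idx.skips, reference)
    return FeatureVector(
        skip_ratio=skip_ratio,
        len_skip=len_skip,
        group_num=group_num,
        std_start=std_start,
        std_end=std_end,
        gc_skip=gc_skip,
        bp_start=bp_start,
        bp_end=bp_end,
    )


def features_to_frame(
    rows: Sequence[tuple[GenomicInterval, FeatureVector]],
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Tabulate windows as a DataFrame: provenance columns, 38 features, label."""
    records = []
    for k, (iv, fv) in enumerate(rows):
        rec = {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
        rec.update(fv.to_series().to_dict())
        if labels is not None:
            rec["label"] = int(labels[k])
        records.append(rec)
    cols = ["chrom", "start", "end", *FEATURE_NAMES]
    if labels is not None:
        cols.append("label")
    return pd.DataFrame.from_records(records, columns=cols)


def write_feature_table(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
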