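"""Parsing of spliced long-read alignments and A-to-I editing-site catalogs.

Long-read cDNA alignments contain internal "skips" — reference segments the
read jumps over, encoded either as ``~`` items in a minimap2 ``cs`` difference
string or as ``N`` operations in the CIGAR. Genuine introns and
reverse-transcriptase template-switching artifacts both surface this way; this
module extracts the raw skip events and counts reads per genomic window so
that downstream feature extraction can tell the two apart.

Coordinates are 0-based half-open throughout. Editing catalogs (REDIportal
style, 1-based positions) are converted on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import pysam

#: Skips shorter than this are treated as small deletions, not region-skipping.
DEFAULT_MIN_SKIP_LENGTH = 20

_VALID_STRANDS = frozenset("+-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in nt between two non-overlapping intervals (0 if abutting/overlapping)."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class SkipEvent:
    """One internal skipped reference segment within one read."""

    read_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"skip end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignedRead:
    """One primary alignment with its internal skip events."""

    read_id: str
    chrom: str
    aln_start: int
    aln_end: int
    skips: list[SkipEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = self.aln_start
        for sk in self.skips:
            if sk.start < self.aln_start or sk.end > self.aln_end:
                raise ValueError(
                    f"skip [{sk.start}, {sk.end}) outside alignment span "
                    f"[{self.aln_start}, {self.aln_end}) of read {self.read_id}"
                )
            if sk.start < prev_end:
                raise ValueError(f"skips of read {self.read_id} overlap or are unsorted")
            prev_end = sk.end


@dataclass(frozen=True, order=True)
class EditingSite:
    """A known A-to-I editing position (0-based)."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


# --- cs tag / CIGAR skip extraction -------------------------------------------------

# Short and long form cs tokens. The "~" item is  ~<2 donor bases><len><2 acceptor bases>
# where <len> is the full length of the skipped reference segment (motif included).
_CS_TOKEN = re.compile(
    r"(:\d+)|(\*[a-zA-Z]{2})|(\+[a-zA-Z]+)|(-[a-zA-Z]+)|(~[a-zA-Z]{2}\d+[a-zA-Z]{2})|(=[A-Za-z]+)"
)

_REF_CONSUMING_CIGAR_OPS = {0, 2, 3, 7, 8}  # M, D, N, =, X
_CIGAR_N = 3


def parse_cs_skips(cs: str, ref_start: int, read_id: str, chrom: str) -> list[SkipEvent]:
    """Extract skip events from a minimap2 cs difference string.

    Walks the string replaying reference consumption; each ``~`` item yields one
    :class:`SkipEvent` at the current reference offset.
    """
    pos = ref_start
    events: list[SkipEvent] = []
    i = 0
    while i < len(cs):
        m = _CS_TOKEN.match(cs, i)
        if m is None:
            raise ValueError(f"malformed cs tag at offset {i}: {cs[i:i + 12]!r}")
        tok = m.group(0)
        op = tok[0]
        if op == ":":
            pos += int(tok[1:])
        elif op == "=":
            pos += len(tok) - 1
        elif op == "*":
            pos += 1
        elif op == "-":
            pos += len(tok) - 1
        elif op == "~":
            length = int(tok[3:-2])
            if length < 1:
                raise ValueError(f"malformed cs tag: zero-length skip {tok!r}")
            events.append(SkipEvent(read_id, chrom, pos, pos + length))
            pos += length
        # "+" consumes no reference
        i = m.end()
    return events


def parse_cigar_skips(
    cigartuples: Sequence[tuple[int, int]], ref_start: int, read_id: str, chrom: str
) -> list[SkipEvent]:
    """Extract skip events from CIGAR N operations."""
    pos = ref_start
    events: list[SkipEvent] = []
    for op, length in cigartuples:
        if op == _CIGAR_N:
            events.append(SkipEvent(read_id, chrom, pos, pos + length))
        if op in _REF_CONSUMING_CIGAR_OPS:
            pos += length
    return events


def parse_skip_events(record: pysam.AlignedSegment) -> list[SkipEvent]:
    """Skip events of one mapped primary record.

    The cs tag, when present, takes precedence over the CIGAR; both encode the
    same alignment, but the cs tag is what the aligner intended. Unmapped
    records are a caller error, not an empty result.
    """
    if record.is_unmapped:
        raise ValueError(f"unmapped record {record.query_name!r}")
    chrom = record.reference_name
    read_id = record.query_name
    if record.has_tag("cs"):
        return parse_cs_skips(record.get_tag("cs"), record.reference_start, read_id, chrom)
    if record.cigartuples is None:
        return []
    return parse_cigar_skips(record.cigartuples, record.reference_start, read_id, chrom)


def read_alignments(
    path: str,
    region: GenomicInterval | None = None,
    min_mapq: int = 0,
) -> Iterator[AlignedRead]:
    """Iterate primary mapped alignments as :class:`AlignedRead`.

    Secondary and supplementary records are excluded so each molecule votes
    once. ``region`` restricts iteration (requires an index for BAM random
    access; SAM files are streamed and filtered).
    """
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as fh:
        if region is not None and fh.has_index():
            records: Iterable[pysam.AlignedSegment] = fh.fetch(
                region.chrom, region.start, region.end
            )
        else:
            records = fh.fetch(until_eof=True)
        for rec in records:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if region is not None and (
                rec.reference_name != region.chrom
                or rec.reference_end <= region.start
                or rec.reference_start >= region.end
            ):
                continue
            yield AlignedRead(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                aln_start=rec.reference_start,
                aln_end=rec.reference_end,
                skips=parse_skip_events(rec),
            )


class WindowIndex(NamedTuple):
    """Read/skip tallies of one genomic window."""

    total_reads: int
    skipping_reads: int
    skips: list[SkipEvent]


def index_reads_by_window(
    reads: Iterable[AlignedRead],
    window: GenomicInterval,
    min_skip_length: int = DEFAULT_MIN_SKIP_LENGTH,
) -> WindowIndex:
    """Count reads overlapping a window and collect their in-window skips.

    A read counts toward ``total_reads`` when its alignment span overlaps the
    window by at least one base. A skip belongs to the window when its *start*
    coordinate falls inside it (single unambiguous assignment for skips that
    straddle window edges); skips shorter than ``min_skip_length`` are ignored
    as small deletions. A read with several qualifying skips counts once in
    ``skipping_reads`` but contributes every event.
    """
    total = 0
    skipping = 0
    events: list[SkipEvent] = []
    for read in reads:
        if read.chrom != window.chrom:
            continue
        if read.aln_end <= window.start or read.aln_start >= window.end:
            continue
        total += 1
        read_events = [
            sk
            for sk in read.skips
            if sk.length >= min_skip_length and window.contains(sk.chrom, sk.start)
        ]
        if read_events:
            skipping += 1
            events.extend(read_events)
    return WindowIndex(total, skipping, events)


def load_editing_sites(
    path: str,
    chrom_col: int = 0,
    pos_col: int = 1,
    strand_col: int = 2,
    sep: str = "\t",
) -> dict[str, list[EditingSite]]:
    """Load a tab-separated editing-site catalog (1-based positions).

    Returns sites per chromosome, deduplicated and sorted ascending by
    position. A header row is tolerated when its position field is
    non-numeric; any later unparseable line raises with its line number.
    """
    sites: set[EditingSite] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(sep)
            try:
                chrom = fields[chrom_col]
                pos_text = fields[pos_col]
                strand = fields[strand_col]
            except IndexError:
                raise ValueError(f"line {lineno}: too few columns in {path}") from None
            if lineno == 1 and not pos_text.lstrip("-").isdigit():
                continue  # header
            try:
                pos = int(pos_text)
            except ValueError:
                raise ValueError(
                    f"line {lineno}: non-numeric position {pos_text!r} in {path}"
                ) from None
            if strand not in _VALID_STRANDS:
                raise ValueError(
                    f"line {lineno}: unknown strand symbol {strand!r} in {path}"
                )
            if pos < 1:
                raise ValueError(f"line {lineno}: 1-based position must be >= 1")
            sites.add(EditingSite(chrom, pos - 1, strand))
    catalog: dict[str, list[EditingSite]] = {}
    for site in sorted(sites):
        catalog.setdefault(site.chrom, []).append(site)
    return catalog
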