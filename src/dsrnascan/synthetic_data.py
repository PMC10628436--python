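"""Seeded simulation of genomes, spliced long-read alignments and editing
catalogs with planted ground truth.

The generator emulates the two skip archetypes the classifier must
distinguish:

* **dsRNA loci** — an inverted repeat (arm + loop + reverse-complement arm)
  planted in random background; each read over the locus independently
  skips the hairpin at a low per-molecule frequency, with motif-free
  boundaries jittered around the true arm ends (template switching does not
  honour splice signals and its breakpoints wander between molecules);
* **splice loci** — an intron with exact GT..AG junctions; every read of a
  locus skips it with a locus-level inclusion probability drawn from a
  bimodal Beta, so the corpus-wide skipping-ratio distribution of spliced
  windows is bimodal while that of dsRNA windows stays unimodal and low.

dsRNA loci additionally carry clustered A-to-I editing sites within their
arms; the corresponding A->G substitutions are planted directly into the
simulated read sequences so editing-index computation sees realistic
pileups. Reads are emitted pre-aligned (SAM records carrying both a CIGAR
with N operations and the matching cs difference string); every artifact is
byte-reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .alignment_io import AlignedRead, EditingSite, GenomicInterval, SkipEvent
from .feature_extraction import extract_features, features_to_frame, FeatureVector

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated corpus.

    Defaults describe a hairpin-rich locus set at modest long-read coverage:
    arms of 200-600 nt with 50-500 nt loops, template-switch skip
    frequencies of 2-20% per molecule with 30-nt boundary jitter, splice
    inclusion drawn from Beta(0.3, 0.3), and 10-30 clustered editing sites
    per dsRNA locus edited at 10-50%.
    """

    n_dsrna_loci: int = 20
    n_splice_loci: int = 20
    n_background_loci: int = 0
    genome_length: int | None = None  # None: sized to fit the loci
    chrom: str = "chr1"
    arm_length_range: tuple[int, int] = (200, 600)
    loop_length_range: tuple[int, int] = (50, 500)
    skip_fraction_range: tuple[float, float] = (0.02, 0.2)
    boundary_jitter_sd: float = 30.0
    splice_inclusion_beta: tuple[float, float] = (0.3, 0.3)
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (300, 1500)
    mean_coverage: float = 20.0
    read_flank_range: tuple[int, int] = (100, 500)
    editing_sites_range: tuple[int, int] = (10, 30)
    editing_level_range: tuple[float, float] = (0.1, 0.5)
    #: Per-read probability of one additional motif-free skip anywhere in the
    #: read, emulating the error/variant-driven skipping real control regions
    #: show on top of genuine splicing.
    noise_skip_rate: float = 0.03
    noise_skip_length_range: tuple[int, int] = (100, 1500)
    #: Spliced aligners place N gaps preferentially at canonical splice
    #: motifs: a biologically motif-free skip boundary is shifted to a GT
    #: (start) / AG (end) dinucleotide if one lies within this many nt.
    #: Set 0 for an aligner with no such preference. The default reflects the
    #: few-nt placement ambiguity that template-switch microhomology leaves a
    #: spliced aligner on accurate long reads.
    aligner_motif_snap_radius: int = 5
    locus_spacing: int = 2500
    min_skip_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "arm_length_range",
            "loop_length_range",
            "skip_fraction_range",
            "exon_length_range",
            "intron_length_range",
            "read_flank_range",
            "editing_sites_range",
            "editing_level_range",
            "noise_skip_length_range",
        ):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is degenerate: {lo}..{hi}")
        if self.mean_coverage < 6:
            raise ValueError("mean coverage below 6 cannot satisfy the window filter")


@dataclass
class TruthRecord:
    """Ground truth for one planted locus."""

    interval: GenomicInterval
    kind: str  # dsRNA | splice | background
    skip_start: int | None = None  # hairpin span or intron span
    skip_end: int | None = None
    skip_probability: float | None = None  # per-read skip / inclusion probability
    arm_length: int | None = None  # dsRNA loci only
    editing: list[tuple[int, float]] = field(default_factory=list)  # (pos, level)


@dataclass
class SimulatedRead:
    read_id: str
    chrom: str
    start: int
    end: int
    skips: list[tuple[int, int]]  # sorted, non-overlapping
    sequence: str

    def to_aligned_read(self) -> AlignedRead:
        events = [SkipEvent(self.read_id, self.chrom, s, e) for s, e in self.skips]
        return AlignedRead(self.read_id, self.chrom, self.start, self.end, events)


@dataclass
class Corpus:
    config: SimulationConfig
    genome: dict[str, str]
    truth: list[TruthRecord]
    sites: list[EditingSite]
    site_levels: dict[tuple[str, int], float]
    reads: list[SimulatedRead]

    def aligned_reads(self) -> list[AlignedRead]:
        return [r.to_aligned_read() for r in self.reads]


# --- genome -------------------------------------------------------------------------


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, str], list[TruthRecord]]:
    """Random background with planted hairpin and splice loci.

    Loci are laid out left to right in a seed-shuffled kind order with
    ``locus_spacing`` nt of background between them, so truth intervals of
    different kinds never overlap and each fits its own analysis window.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    kinds = (
        ["dsRNA"] * config.n_dsrna_loci
        + ["splice"] * config.n_splice_loci
        + ["background"] * config.n_background_loci
    )
    order = rng.permutation(len(kinds))
    kinds = [kinds[i] for i in order]

    pieces: list[str] = []
    truth: list[TruthRecord] = []
    cursor = 0

    def emit_background(n: int) -> None:
        nonlocal cursor
        pieces.append("".join(rng.choice(list("ACGT"), size=n)))
        cursor += n

    for kind in kinds:
        emit_background(config.locus_spacing)
        if kind == "dsRNA":
            arm = int(rng.integers(*_incl(config.arm_length_range)))
            loop = int(rng.integers(*_incl(config.loop_length_range)))
            arm_seq = "".join(rng.choice(list("ACGT"), size=arm))
            loop_seq = "".join(rng.choice(list("ACGT"), size=loop))
            locus_seq = arm_seq + loop_seq + reverse_complement(arm_seq)
            start = cursor
            pieces.append(locus_seq)
            cursor += len(locus_seq)
            truth.append(
                TruthRecord(
                    interval=GenomicInterval(config.chrom, start, cursor),
                    kind="dsRNA",
                    skip_start=start,
                    skip_end=cursor,
                    skip_probability=float(rng.uniform(*config.skip_fraction_range)),
                    arm_length=arm,
                )
            )
        elif kind == "splice":
            exon1 = int(rng.integers(*_incl(config.exon_length_range)))
            exon2 = int(rng.integers(*_incl(config.exon_length_range)))
            intron = int(rng.integers(*_incl(config.intron_length_range)))
            e1 = "".join(rng.choice(list("ACGT"), size=exon1))
            e2 = "".join(rng.choice(list("ACGT"), size=exon2))
            inner = "".join(rng.choice(list("ACGT"), size=intron - 4))
            intron_seq = "GT" + inner + "AG"
            start = cursor
            pieces.append(e1 + intron_seq + e2)
            cursor += exon1 + intron + exon2
            a, b = config.splice_inclusion_beta
            truth.append(
                TruthRecord(
                    interval=GenomicInterval(config.chrom, start, cursor),
                    kind="splice",
                    skip_start=start + exon1,
                    skip_end=start + exon1 + intron,
                    skip_probability=float(rng.beta(a, b)),
                )
            )
        else:  # background locus: covered by reads but skip-free
            length = int(rng.integers(*_incl(config.intron_length_range)))
            start = cursor
            emit_background(length)
            truth.append(
                TruthRecord(GenomicInterval(config.chrom, start, cursor), "background")
            )
    emit_background(config.locus_spacing)

    needed = cursor
    if config.genome_length is not None:
        if config.genome_length < needed:
            raise ValueError(
                f"genome_length {config.genome_length} cannot fit the requested "
                f"loci (need >= {needed} nt)"
            )
        emit_background(config.genome_length - needed)
    return {config.chrom: "".join(pieces)}, truth


def _incl(rng_pair: tuple[int, int]) -> tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


# --- editing sites ------------------------------------------------------------------


def simulate_editing_sites(
    genome: dict[str, str],
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[EditingSite], dict[tuple[str, int], float]]:
    """Plant clustered A-to-I sites within the arms of each dsRNA locus.

    Site positions are adenosines of the reference; each locus receives a
    configured number of sites placed so that at least one triple falls
    within a 50-nt span (the enrichment rule downstream curation relies on).
    Per-site editing levels are drawn from the configured range and recorded
    on the truth records for read simulation. Background and splice loci
    receive no sites.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    sites: list[EditingSite] = []
    levels: dict[tuple[str, int], float] = {}
    for rec in truth:
        if rec.kind != "dsRNA":
            continue
        chrom_seq = genome[rec.interval.chrom]
        hs, he = rec.skip_start, rec.skip_end
        arm = rec.arm_length
        arm_positions = [
            p
            for p in range(hs, hs + arm)
            if chrom_seq[p] == "A"
        ] + [p for p in range(he - arm, he) if chrom_seq[p] == "A"]
        if len(arm_positions) < 3:
            logger.warning(
                "locus %s has only %d adenosines in its arms; skipping sites",
                rec.interval, len(arm_positions),
            )
            continue
        n_sites = int(rng.integers(*_incl(config.editing_sites_range)))
        chosen: set[int] = set()
        triple = _first_dense_triple(arm_positions, span=50)
        if triple is None:
            logger.warning("locus %s lacks 3 adenosines within 50 nt", rec.interval)
        else:
            chosen.update(triple)
        remaining = [p for p in arm_positions if p not in chosen]
        extra = max(0, min(n_sites - len(chosen), len(remaining)))
        if extra:
            chosen.update(
                int(p) for p in rng.choice(remaining, size=extra, replace=False)
            )
        if len(chosen) < n_sites:
            logger.warning(
                "locus %s: planted %d/%d editing sites (adenosine-limited)",
                rec.interval, len(chosen), n_sites,
            )
        for pos in sorted(chosen):
            level = float(rng.uniform(*config.editing_level_range))
            sites.append(EditingSite(rec.interval.chrom, pos, "+"))
            levels[(rec.interval.chrom, pos)] = level
            rec.editing.append((pos, level))
    return sorted(sites), levels


def _first_dense_triple(positions: Sequence[int], span: int) -> list[int] | None:
    pos = sorted(positions)
    for i in range(len(pos) - 2):
        if pos[i + 2] - pos[i] < span:
            return [pos[i], pos[i + 1], pos[i + 2]]
    return None


# --- reads --------------------------------------------------------------------------


def simulate_alignments(
    genome: dict[str, str],
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Simulate pre-aligned reads per locus.

    Coverage per locus is Poisson(mean_coverage). dsRNA reads skip the
    hairpin with the locus skip fraction at Normal-jittered boundaries;
    splice reads skip the intron exactly at the GT/AG junctions with the
    locus inclusion probability. Independently, any read may carry one
    motif-free noise skip (rate ``noise_skip_rate``), standing in for the
    error/variant-driven skipping seen in real control regions. Editing
    sites are substituted A->G in each covering, non-skipping-over read with
    the planted per-site level.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    reads: list[SimulatedRead] = []
    for li, rec in enumerate(truth):
        chrom = rec.interval.chrom
        chrom_seq = genome[chrom]
        chrom_len = len(chrom_seq)
        n_reads = int(rng.poisson(config.mean_coverage))
        for ri in range(n_reads):
            f1 = int(rng.integers(*_incl(config.read_flank_range)))
            f2 = int(rng.integers(*_incl(config.read_flank_range)))
            rs = max(0, rec.interval.start - f1)
            re_ = min(chrom_len, rec.interval.end + f2)
            skips: list[tuple[int, int]] = []
            if rec.kind == "splice":
                if rng.random() < rec.skip_probability:
                    skips.append((rec.skip_start, rec.skip_end))
            elif rec.kind == "dsRNA":
                if rng.random() < rec.skip_probability:
                    skips.append(
                        _jittered_skip(rec, rs, re_, chrom_seq, config, rng)
                    )
            if rng.random() < config.noise_skip_rate:
                noise = _noise_skip(rs, re_, skips, chrom_seq, config, rng)
                if noise is not None:
                    skips.append(noise)
                    skips.sort()
            read_id = f"{rec.kind}_{li:04d}_{ri:04d}"
            seq = _read_sequence(chrom_seq, rs, re_, skips, rec, rng)
            reads.append(SimulatedRead(read_id, chrom, rs, re_, skips, seq))
    reads.sort(key=lambda r: (r.chrom, r.start, r.read_id))
    return reads


def _noise_skip(
    rs: int,
    re_: int,
    existing: list[tuple[int, int]],
    chrom_seq: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_tries: int = 10,
) -> tuple[int, int] | None:
    lo, hi = config.noise_skip_length_range
    for _ in range(max_tries):
        length = int(rng.integers(lo, hi + 1))
        if re_ - rs < length + 20:
            continue
        ss = int(rng.integers(rs + 10, re_ - length - 10 + 1))
        se = ss + length
        ss, se = _snap_to_motif(ss, se, chrom_seq, config)
        if se - ss < config.min_skip_length:
            continue
        if all(se <= s or e <= ss for s, e in existing):
            return ss, se
    return None


def _snap_to_motif(
    ss: int, se: int, chrom_seq: str, config: SimulationConfig
) -> tuple[int, int]:
    """Emulate spliced-aligner boundary placement.

    Aligners that model introns score canonical splice motifs favourably and
    will shift a gap boundary by a few nt to sit on GT (donor side) / AG
    (acceptor side) when possible — even for gaps that are biochemical
    artifacts. The nearest motif within the configured radius wins.
    """
    radius = config.aligner_motif_snap_radius
    if radius <= 0:
        return ss, se
    for delta in sorted(range(-radius, radius + 1), key=lambda d: (abs(d), d)):
        p = ss + delta
        if 0 <= p and chrom_seq[p : p + 2] == "GT":
            ss = p
            break
    for delta in sorted(range(-radius, radius + 1), key=lambda d: (abs(d), d)):
        p = se + delta
        if p <= len(chrom_seq) and chrom_seq[p - 2 : p] == "AG":
            se = p
            break
    return ss, se


def _jittered_skip(
    rec: TruthRecord,
    rs: int,
    re_: int,
    chrom_seq: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_tries: int = 30,
) -> tuple[int, int]:
    sd = config.boundary_jitter_sd
    for _ in range(max_tries):
        ss = int(round(rng.normal(rec.skip_start, sd)))
        se = int(round(rng.normal(rec.skip_end, sd)))
        ss, se = _snap_to_motif(ss, se, chrom_seq, config)
        if rs + 10 <= ss and se <= re_ - 10 and se - ss >= config.min_skip_length:
            return ss, se
    return rec.skip_start, rec.skip_end  # fall back to the exact hairpin span


def _segments(rs: int, re_: int, skips: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Aligned (non-skipped) reference segments of a read."""
    segments = []
    pos = rs
    for ss, se in skips:
        segments.append((pos, ss))
        pos = se
    segments.append((pos, re_))
    return segments


def _read_sequence(
    chrom_seq: str,
    rs: int,
    re_: int,
    skips: Sequence[tuple[int, int]],
    rec: TruthRecord,
    rng: np.random.Generator,
) -> str:
    out: list[str] = []
    for seg_start, seg_end in _segments(rs, re_, skips):
        bases = list(chrom_seq[seg_start:seg_end])
        for pos, level in rec.editing:
            if seg_start <= pos < seg_end and rng.random() < level:
                bases[pos - seg_start] = "G"
        out.append("".join(bases))
    return "".join(out)


# --- corpus assembly and serialization ----------------------------------------------


def simulate_corpus(config: SimulationConfig) -> Corpus:
    """Genome, editing catalog and reads, fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    genome, truth = simulate_genome(config, rng)
    sites, levels = simulate_editing_sites(genome, truth, config, rng)
    reads = simulate_alignments(genome, truth, config, rng)
    return Corpus(config, genome, truth, sites, levels, reads)


def cs_string(chrom_seq: str, read: SimulatedRead) -> str:
    """minimap2-style (short form) cs difference string for a simulated read."""
    parts: list[str] = []
    segments = _segments(read.start, read.end, read.skips)
    offset = 0
    for k, (seg_start, seg_end) in enumerate(segments):
        if k > 0:
            ss, se = read.skips[k - 1]
            donor = chrom_seq[ss : ss + 2].lower()
            acceptor = chrom_seq[se - 2 : se].lower()
            parts.append(f"~{donor}{se - ss}{acceptor}")
        run = 0
        for i in range(seg_start, seg_end):
            ref_base = chrom_seq[i]
            read_base = read.sequence[offset]
            offset += 1
            if read_base == ref_base:
                run += 1
            else:
                if run:
                    parts.append(f":{run}")
                    run = 0
                parts.append(f"*{ref_base.lower()}{read_base.lower()}")
        if run:
            parts.append(f":{run}")
    return "".join(parts)


def cigar_string(read: SimulatedRead) -> str:
    parts = []
    pos = read.start
    for ss, se in read.skips:
        parts.append(f"{ss - pos}M{se - ss}N")
        pos = se
    parts.append(f"{read.end - pos}M")
    return "".join(parts)


def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_sam(corpus: Corpus, path: str) -> None:
    """Coordinate-sorted SAM; every record carries both CIGAR N and cs tag."""
    chroms = sorted(corpus.genome)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(corpus.genome[c])} for c in chroms],
        }
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for read in corpus.reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.read_id
            seg.flag = 0
            seg.reference_id = chroms.index(read.chrom)
            seg.reference_start = read.start
            seg.mapping_quality = 60
            seg.cigarstring = cigar_string(read)
            seg.query_sequence = read.sequence
            seg.set_tag("cs", cs_string(corpus.genome[read.chrom], read))
            out.write(seg)


def write_sites_tsv(corpus: Corpus, path: str) -> None:
    """1-based editing catalog with planted editing levels."""
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\tlevel\n")
        for site in corpus.sites:
            level = corpus.site_levels[(site.chrom, site.pos)]
            fh.write(f"{site.chrom}\t{site.pos + 1}\t{site.strand}\t{level:.4f}\n")


def write_truth_bed(corpus: Corpus, path: str) -> None:
    with open(path, "w") as fh:
        for rec in corpus.truth:
            fh.write(
                f"{rec.interval.chrom}\t{rec.interval.start}\t{rec.interval.end}\t"
                f"{rec.kind}\t0\t+\n"
            )


def write_corpus(corpus: Corpus, out_dir: str) -> dict[str, str]:
    """Write a self-contained corpus directory; returns the path manifest."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, "genome.fa"),
        "sam": os.path.join(out_dir, "reads.sam"),
        "sites": os.path.join(out_dir, "sites.tsv"),
        "truth": os.path.join(out_dir, "truth.bed"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_fasta(corpus.genome, paths["fasta"])
    write_sam(corpus, paths["sam"])
    write_sites_tsv(corpus, paths["sites"])
    write_truth_bed(corpus, paths["truth"])
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(corpus.config)},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return paths


# --- labeled windows for training/evaluation ----------------------------------------


def truth_window(
    rec: TruthRecord, window_size: int, chrom_len: int
) -> GenomicInterval:
    """The analysis window centred on a planted locus."""
    center = (rec.interval.start + rec.interval.end) // 2
    start = max(0, center - window_size // 2)
    end = min(chrom_len, start + window_size)
    start = max(0, end - window_size)
    return GenomicInterval(rec.interval.chrom, start, end)


def labeled_window_table(
    corpus: Corpus,
    window_size: int = 2500,
    min_reads: int = 6,
) -> pd.DataFrame:
    """Feature rows for every planted dsRNA (label 1) and splice (label 0)
    locus whose window passes the read-support filter."""
    from .alignment_io import index_reads_by_window

    reads = corpus.aligned_reads()
    rows: list[tuple[GenomicInterval, FeatureVector]] = []
    labels: list[int] = []
    for rec in corpus.truth:
        if rec.kind not in ("dsRNA", "splice"):
            continue
        chrom_len = len(corpus.genome[rec.interval.chrom])
        win = truth_window(rec, window_size, chrom_len)
        idx = index_reads_by_window(
            reads, win, min_skip_length=corpus.config.min_skip_length
        )
        if idx.total_reads < min_reads or idx.skipping_reads < 1:
            continue
        rows.append((win, extract_features(win, reads, corpus.genome)))
        labels.append(1 if rec.kind == "dsRNA" else 0)
    return features_to_frame(rows, labels)
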