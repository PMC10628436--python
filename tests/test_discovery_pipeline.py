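"""Window tiling, scoring/exclusion rules, editing index, export."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam
import pytest

from dsrnascan.alignment_io import AlignedRead, EditingSite, GenomicInterval, SkipEvent
from dsrnascan.classifier import ModelConfig, TrainingSet, train_model
from dsrnascan.discovery_pipeline import (
    CandidateWindow,
    compute_editing_index,
    discover_dsrna,
    enumerate_candidate_windows,
    export_results,
    window_starts,
)
from dsrnascan.feature_extraction import FEATURE_NAMES
from dsrnascan.structure_curation import FoldResult
from dsrnascan.synthetic_data import (
    SimulationConfig,
    labeled_window_table,
    simulate_corpus,
    truth_window,
)


class TestWindowStarts:
    def test_five_kb_chromosome(self):
        assert window_starts(5000, 2500, 1250) == [0, 1250, 2500]

    def test_trailing_partial_kept_when_it_adds_coverage(self):
        # 3000 nt: window at 1250 covers 1250..3000 (1750 nt > one stride)
        assert window_starts(3000, 2500, 1250) == [0, 1250]

    def test_short_chromosome_single_window(self):
        assert window_starts(2000, 2500, 1250) == [0]

    def test_every_base_covered_once_or_twice(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            length = int(rng.integers(1500, 30000))
            starts = window_starts(length, 2500, 1250)
            cover = np.zeros(length, dtype=int)
            for s in starts:
                cover[s : min(s + 2500, length)] += 1
            assert cover.min() >= 1
            assert cover.max() <= 2


def _reads(n_total, n_skipping, win_start=0):
    reads = []
    for i in range(n_total):
        skips = []
        if i < n_skipping:
            skips = [SkipEvent(f"r{i}", "chr1", win_start + 500, win_start + 1000)]
        reads.append(AlignedRead(f"r{i}", "chr1", win_start, win_start + 2400, skips))
    return reads


class TestEnumerateCandidateWindows:
    def test_read_support_boundary(self):
        genome = {"chr1": "ACGT" * 1250}  # 5000 nt
        passing = enumerate_candidate_windows(genome, _reads(6, 1))
        failing = enumerate_candidate_windows(genome, _reads(5, 1))
        no_skip = enumerate_candidate_windows(genome, _reads(6, 0))
        assert len(passing) >= 1
        assert failing == []
        assert no_skip == []

    def test_only_covered_windows_appear(self, small_corpus):
        reads = small_corpus.aligned_reads()
        cands = enumerate_candidate_windows(small_corpus.genome, reads)
        assert len(cands) > 0
        for c in cands:
            covering = [
                r
                for r in reads
                if r.aln_start < c.interval.end and r.aln_end > c.interval.start
            ]
            assert len(covering) >= 6


@dataclass
class _StubForest:
    """Deterministic probability: reads the skip_ratio column directly."""

    def predict_proba(self, X):
        p = np.asarray(X)[:, list(FEATURE_NAMES).index("skip_ratio")]
        return np.column_stack([1 - p, p])


@dataclass
class _StubModel:
    forest: _StubForest
    feature_names: tuple = tuple(FEATURE_NAMES)


def _stub_fold(seq: str) -> FoldResult:
    return FoldResult(len(seq), "." * len(seq), 0.0)


def _candidate(start, skip_ratio, chrom="chr1"):
    from dsrnascan.feature_extraction import DINUCLEOTIDES, FeatureVector

    fv = FeatureVector(
        skip_ratio=skip_ratio,
        len_skip=500.0,
        group_num=1.0,
        std_start=0.0,
        std_end=0.0,
        gc_skip=0.5,
        bp_start={d: 0.0 for d in DINUCLEOTIDES},
        bp_end={d: 0.0 for d in DINUCLEOTIDES},
    )
    return CandidateWindow(GenomicInterval(chrom, start, start + 2500), fv)


class TestDiscoverDsrna:
    GENOME = {"chr1": "A" * 20000}

    def test_threshold_is_strict(self):
        model = _StubModel(_StubForest())
        out = discover_dsrna(
            [_candidate(0, 0.49), _candidate(2500, 0.5), _candidate(5000, 0.51)],
            model, [], self.GENOME, fold=_stub_fold,
        )
        assert [r.interval.start for r in out] == [5000]

    def test_positive_overlap_excluded(self):
        model = _StubModel(_StubForest())
        out = discover_dsrna(
            [_candidate(0, 0.9), _candidate(5000, 0.9)],
            model,
            [GenomicInterval("chr1", 2499, 2600)],  # 1-nt overlap with first
            self.GENOME, fold=_stub_fold,
        )
        assert [r.interval.start for r in out] == [5000]

    def test_sorted_by_probability_descending(self):
        model = _StubModel(_StubForest())
        out = discover_dsrna(
            [_candidate(0, 0.6), _candidate(5000, 0.9), _candidate(10000, 0.7)],
            model, [], self.GENOME, fold=_stub_fold,
        )
        assert [r.probability for r in out] == [0.9, 0.7, 0.6]

    def test_folding_failure_skips_window(self):
        def broken(seq):
            raise ValueError("boom")

        model = _StubModel(_StubForest())
        out = discover_dsrna(
            [_candidate(0, 0.9)], model, [], self.GENOME, fold=broken
        )
        assert out == []

    def test_planted_hairpins_recovered_across_seeds(self, training_corpus):
        """Model-positive windows hit planted dsRNA loci and mostly avoid
        splice loci on unseen corpora (structure check stubbed for speed).

        Training follows the real pipeline: positive windows over the
        curated regions, controls sampled at random from read-supported
        windows elsewhere.
        """
        from dsrnascan.classifier import curate_training_set
        from dsrnascan.eer_annotation import CuratedDsRNA
        from dsrnascan.structure_curation import FoldResult, StemReport

        positives = [
            CuratedDsRNA(
                interval=t.interval,
                fold=FoldResult(t.interval.length, "." * t.interval.length, -900.0),
                stem=StemReport(300, 0.05),
            )
            for t in training_corpus.truth
            if t.kind == "dsRNA"
        ]
        ts = curate_training_set(
            positives,
            training_corpus.genome,
            training_corpus.aligned_reads(),
            seed=0,
        )
        model = train_model(ts, ModelConfig(random_seed=0))
        recalls, specs = [], []
        for seed in range(101, 106):
            corpus = simulate_corpus(
                SimulationConfig(n_dsrna_loci=12, n_splice_loci=12, seed=seed)
            )
            reads = corpus.aligned_reads()
            cands = enumerate_candidate_windows(corpus.genome, reads)
            regions = discover_dsrna(cands, model, [], corpus.genome, fold=_stub_fold)

            def visible(t):
                """Loci inside the discovery universe: >= 1 candidate window.

                A hairpin whose reads never skip is removed by the >= 1-skip
                candidate filter itself, not by the classifier."""
                return any(c.interval.overlaps(t.interval) for c in cands)

            def hit(t):
                return any(r.interval.overlaps(t.interval) for r in regions)

            ds = [t for t in corpus.truth if t.kind == "dsRNA" and visible(t)]
            sp = [t for t in corpus.truth if t.kind == "splice" and visible(t)]
            recalls.append(sum(hit(t) for t in ds) / len(ds))
            specs.append(1 - sum(hit(t) for t in sp) / len(sp))
        assert float(np.mean(recalls)) >= 0.8
        assert float(np.mean(specs)) >= 0.8

    def test_no_discovery_overlaps_curated_positive(self, training_corpus):
        model = train_model(
            TrainingSet(labeled_window_table(training_corpus)),
            ModelConfig(random_seed=0),
        )
        corpus = simulate_corpus(
            SimulationConfig(n_dsrna_loci=10, n_splice_loci=10, seed=202)
        )
        positives = [
            truth_window(t, 2500, len(corpus.genome["chr1"]))
            for t in corpus.truth
            if t.kind == "dsRNA"
        ][:5]
        cands = enumerate_candidate_windows(corpus.genome, corpus.aligned_reads())
        regions = discover_dsrna(cands, model, positives, corpus.genome, fold=_stub_fold)
        for r in regions:
            assert not any(r.interval.overlaps(p) for p in positives)


# --- editing index ------------------------------------------------------------------


def _sam_with_pileup(tmp_path, bases_by_read, site_pos=100, chrom_len=1000):
    """Reads of 200M covering [0,200); each contributes one base at site_pos."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": "chr1", "LN": chrom_len}]}
    )
    path = tmp_path / "pileup.bam"
    with pysam.AlignmentFile(str(path), "wb", header=header) as out:
        for i, base in enumerate(bases_by_read):
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"p{i}"
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = 0
            rec.mapping_quality = 60
            rec.cigarstring = "200M"
            rec.query_sequence = "A" * site_pos + base + "A" * (200 - site_pos - 1)
            out.write(rec)
    pysam.index(str(path))
    return str(path)


class TestComputeEditingIndex:
    REGION = GenomicInterval("chr1", 0, 200)

    def test_basic_ratio(self, tmp_path):
        bam = _sam_with_pileup(tmp_path, ["A"] * 6 + ["G"] * 2)
        res = compute_editing_index(
            self.REGION, bam, [EditingSite("chr1", 100, "+")]
        )
        assert res.index == pytest.approx(0.25)
        assert (res.a_count, res.g_count) == (6, 2)

    def test_coverage_boundary_strictly_more_than_three(self, tmp_path):
        d3 = tmp_path / "three"
        d4 = tmp_path / "four"
        d3.mkdir()
        d4.mkdir()
        bam3 = _sam_with_pileup(d3, ["G"] * 3)
        res3 = compute_editing_index(self.REGION, bam3, [EditingSite("chr1", 100, "+")])
        assert res3.index is None and res3.n_sites_used == 0
        bam4 = _sam_with_pileup(d4, ["G"] * 4)
        res4 = compute_editing_index(self.REGION, bam4, [EditingSite("chr1", 100, "+")])
        assert res4.index == 1.0 and res4.n_sites_used == 1

    def test_no_qualifying_sites_is_missing_not_zero(self, tmp_path):
        bam = _sam_with_pileup(tmp_path, ["A"] * 8)
        res = compute_editing_index(self.REGION, bam, [])
        assert res.index is None

    def test_minus_strand_counts_complement(self, tmp_path):
        bam = _sam_with_pileup(tmp_path, ["T"] * 4 + ["C"] * 4)
        res = compute_editing_index(
            self.REGION, bam, [EditingSite("chr1", 100, "-")]
        )
        assert res.index == pytest.approx(0.5)

    def test_skipped_reads_do_not_cover_site(self, tmp_path):
        """A read whose N gap spans the site contributes no coverage there."""
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "coordinate"},
             "SQ": [{"SN": "chr1", "LN": 1000}]}
        )
        path = tmp_path / "skip.bam"
        with pysam.AlignmentFile(str(path), "wb", header=header) as out:
            for i in range(4):
                rec = pysam.AlignedSegment(header)
                rec.query_name = f"s{i}"
                rec.flag = 0
                rec.reference_id = 0
                rec.reference_start = 0
                rec.mapping_quality = 60
                rec.cigarstring = "50M100N50M"
                rec.query_sequence = "G" * 100
                out.write(rec)
        pysam.index(str(path))
        res = compute_editing_index(
            GenomicInterval("chr1", 0, 200), str(path), [EditingSite("chr1", 100, "+")]
        )
        assert res.n_sites_used == 0 and res.index is None


class TestExportResults:
    def _region(self, start, prob, cls_novel=True):
        from dsrnascan.discovery_pipeline import DiscoveredRegion
        from dsrnascan.structure_curation import StemReport, StructureClass

        return DiscoveredRegion(
            interval=GenomicInterval("chr1", start, start + 2500),
            probability=prob,
            structure_class=(
                StructureClass.NOVEL_LONG_DSRNA if cls_novel else StructureClass.STRUCTURED_RNA
            ),
            fold=FoldResult(2500, "." * 2500, -900.0),
            stem=StemReport(250, 0.1),
        )

    def test_empty_outputs_are_valid(self, tmp_path):
        bed, tsv = tmp_path / "o.bed", tmp_path / "o.tsv"
        export_results([], str(bed), str(tsv))
        assert bed.read_text() == ""
        assert tsv.read_text().startswith("chrom\tstart\tend\tprobability")

    def test_bed_score_rounding(self, tmp_path):
        bed, tsv = tmp_path / "o.bed", tmp_path / "o.tsv"
        export_results([self._region(0, 0.876)], str(bed), str(tsv))
        fields = bed.read_text().strip().split("\t")
        assert fields[4] == "876"
        assert fields[3] == "novel_long_dsRNA"

    def test_byte_identical_reruns(self, tmp_path):
        regions = [self._region(0, 0.876), self._region(5000, 0.61, cls_novel=False)]
        out1 = tmp_path / "a.bed", tmp_path / "a.tsv"
        out2 = tmp_path / "b.bed", tmp_path / "b.tsv"
        export_results(regions, str(out1[0]), str(out1[1]))
        export_results(regions, str(out2[0]), str(out2[1]))
        assert out1[0].read_bytes() == out2[0].read_bytes()
        assert out1[1].read_bytes() == out2[1].read_bytes()
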