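"""Stub scoring model, stub folding engine and pileup builders for tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from dsrnascan.alignment_io import GenomicInterval
from dsrnascan.discovery_pipeline import CandidateWindow
from dsrnascan.feature_extraction import DINUCLEOTIDES, FEATURE_NAMES, FeatureVector
from dsrnascan.structure_curation import FoldResult


@dataclass
class _StubForest:
    """Positive-class probability read directly from the skip_ratio column."""

    def predict_proba(self, X):
        p = np.asarray(X)[:, list(FEATURE_NAMES).index("skip_ratio")]
        return np.column_stack([1 - p, p])


@dataclass
class _StubModel:
    forest: _StubForest
    feature_names: tuple = tuple(FEATURE_NAMES)


def stub_model() -> _StubModel:
    return _StubModel(_StubForest())


def stub_fold(seq: str) -> FoldResult:
    """Fixture fold engine: structure-free result, no thermodynamics."""
    return FoldResult(len(seq), "." * len(seq), 0.0)


def candidate(start: int, probability_as_skip_ratio: float, chrom="chr1") -> CandidateWindow:
    fv = FeatureVector(
        skip_ratio=probability_as_skip_ratio,
        len_skip=500.0,
        group_num=1.0,
        std_start=0.0,
        std_end=0.0,
        gc_skip=0.5,
        bp_start={d: 0.0 for d in DINUCLEOTIDES},
        bp_end={d: 0.0 for d in DINUCLEOTIDES},
    )
    return CandidateWindow(GenomicInterval(chrom, start, start + 2500), fv)


def pileup_bam(directory, bases, site_pos=100, chrom_len=1000) -> str:
    """Indexed BAM of 200M reads, each placing one base at ``site_pos``."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chr1", "LN": chrom_len}],
        }
    )
    path = str(directory / "pileup.bam")
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for i, base in enumerate(bases):
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"p{i}"
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = 0
            rec.mapping_quality = 60
            rec.cigarstring = "200M"
            rec.query_sequence = "A" * site_pos + base + "A" * (200 - site_pos - 1)
            out.write(rec)
    pysam.index(path)
    return path
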