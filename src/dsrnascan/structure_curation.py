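"""Secondary-structure verification of candidate dsRNA regions.

Candidates that the classifier (or the editing-based curation) flags are
folded with a thermodynamic engine (ViennaRNA's RNAfold) and judged on three
metrics:

* **MFE** — minimum free energy of the predicted structure (kcal/mol);
* **adjusted MFE (AMFE)** — MFE normalised by sequence length, times 100,
  i.e. kcal/mol per 100 nt, making energies comparable across lengths;
* **duplex stem length / mismatch fraction** — size and imperfection of the
  longest near-contiguous double helix in the predicted structure.

A long (>= 200 bp) stem with few interruptions and a strongly negative AMFE
is the signature of the extended duplexes (typically inverted-repeat
derived) that dsRNA sensors such as MDA5 recognise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

DEFAULT_MAX_FOLD_LENGTH = 5000
DEFAULT_MIN_STEM = 200
DEFAULT_MAX_MISMATCH = 0.20
#: AMFE acceptance threshold in kcal/mol per 100 nt.
DEFAULT_AMFE_THRESHOLD = -35.0
#: Interior loops / bulges up to this many nt per side do not break a duplex.
DEFAULT_LOOP_TOLERANCE = 30


class FoldingEngineError(RuntimeError):
    """Raised when the thermodynamic folding engine cannot be used."""


@dataclass(frozen=True)
class FoldResult:
    """Dot-bracket structure of one folded sequence with its energies."""

    sequence_length: int
    dotbracket: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.dotbracket) != self.sequence_length:
            raise ValueError("dot-bracket length must equal sequence length")
        pair_table(self.dotbracket)  # raises if unbalanced

    @property
    def amfe(self) -> float:
        """Adjusted MFE: kcal/mol per 100 nt."""
        return self.mfe / self.sequence_length * 100.0


@dataclass(frozen=True)
class StemReport:
    """Longest duplex found in a dot-bracket structure."""

    length: int  # base pairs in the duplex
    span_mismatch_fraction: float  # unpaired positions within the duplex span

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("stem length must be non-negative")
        if not 0.0 <= self.span_mismatch_fraction <= 1.0:
            raise ValueError("mismatch fraction must lie in [0, 1]")


class StructureClass(str, Enum):
    NOVEL_LONG_DSRNA = "novel_long_dsRNA"
    STRUCTURED_RNA = "structured_RNA"


def fold_sequence(seq: str, max_length: int = DEFAULT_MAX_FOLD_LENGTH) -> FoldResult:
    """Fold a nucleotide sequence and return structure + energies.

    T is mapped to U and case is normalised; N never pairs. Sequences longer
    than ``max_length`` are refused (cubic-time folding).
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} nt, need >= 10)")
    if len(seq) > max_length:
        raise ValueError(
            f"sequence of {len(seq)} nt exceeds folding limit of {max_length} nt"
        )
    if any(b not in "ACGUN" for b in seq):
        bad = next(b for b in seq if b not in "ACGUN")
        raise ValueError(f"sequence contains non-nucleotide character {bad!r}")
    try:
        import RNA
    except ImportError as exc:  # pragma: no cover - environment guard
        raise FoldingEngineError(
            "the ViennaRNA python bindings (module 'RNA') are required for folding; "
            "install the ViennaRNA package"
        ) from exc
    dotbracket, mfe = RNA.fold(seq)
    return FoldResult(sequence_length=len(seq), dotbracket=dotbracket, mfe=float(mfe))


def pair_table(dotbracket: str) -> list[int]:
    """Map each position to its partner (-1 if unpaired); raises on unbalanced input."""
    partner = [-1] * len(dotbracket)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced dot-bracket: unmatched ')' at {i}")
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced dot-bracket: unmatched '(' at {stack[-1]}")
    return partner


def _helices(partner: list[int]) -> list[list[tuple[int, int]]]:
    """Maximal stacks of pairs (i,j),(i+1,j-1),... ordered by outer opening position."""
    pairs = sorted((i, j) for i, j in enumerate(partner) if j > i)
    helices: list[list[tuple[int, int]]] = []
    current: list[tuple[int, int]] = []
    for p in pairs:
        if current and p == (current[-1][0] + 1, current[-1][1] - 1):
            current.append(p)
        else:
            if current:
                helices.append(current)
            current = [p]
    if current:
        helices.append(current)
    return helices


def _chainable(
    h1: list[tuple[int, int]], h2: list[tuple[int, int]], tolerance: int
) -> bool:
    """Can h2 extend h1 inward across an interior loop/bulge of <= tolerance per side?"""
    a, b = h1[-1]  # innermost pair of h1
    c, d = h2[0]  # outermost pair of h2
    return a < c and d < b and (c - a - 1) <= tolerance and (b - d - 1) <= tolerance


def stem_report(
    dotbracket: str, loop_tolerance: int = DEFAULT_LOOP_TOLERANCE
) -> StemReport:
    """Measure the longest duplex in a dot-bracket structure.

    Helices (maximal stacked pair runs) are chained into a duplex as long as
    consecutive helices are separated by interior loops or bulges of at most
    ``loop_tolerance`` nt per side. The duplex maximising the number of base
    pairs is reported. Its span is the two strands of the duplex — the
    positions from the outermost to the innermost pair on each side — so the
    mismatch fraction counts only bulged/interior-loop positions interrupting
    the stem, never whatever the stem encloses (e.g. a hairpin loop).
    """
    partner = pair_table(dotbracket)
    helices = _helices(partner)
    if not helices:
        return StemReport(length=0, span_mismatch_fraction=0.0)
    n = len(helices)
    # best chain starting at helix k (helices are ordered; chaining goes inward,
    # i.e. to helices with a larger outer opening position)
    best_pairs = [0] * n
    successor = [-1] * n
    for k in range(n - 1, -1, -1):
        best_pairs[k] = len(helices[k])
        for m in range(k + 1, n):
            if _chainable(helices[k], helices[m], loop_tolerance):
                cand = len(helices[k]) + best_pairs[m]
                if cand > best_pairs[k]:
                    best_pairs[k] = cand
                    successor[k] = m
    start = max(range(n), key=lambda k: (best_pairs[k], -k))
    length = best_pairs[start]
    last = start
    while successor[last] != -1:
        last = successor[last]
    outer_i, outer_j = helices[start][0]
    inner_i, inner_j = helices[last][-1]
    span = (inner_i - outer_i + 1) + (outer_j - inner_j + 1)
    mismatch = (span - 2 * length) / span
    return StemReport(length=length, span_mismatch_fraction=mismatch)


def classify_structure(
    fold: FoldResult,
    stem: StemReport,
    min_stem: int = DEFAULT_MIN_STEM,
    max_mismatch: float = DEFAULT_MAX_MISMATCH,
    amfe_threshold: float = DEFAULT_AMFE_THRESHOLD,
) -> StructureClass:
    """Novel long dsRNA vs generally structured RNA, inclusive thresholds."""
    if (
        stem.length >= min_stem
        and stem.span_mismatch_fraction <= max_mismatch
        and fold.amfe <= amfe_threshold
    ):
        return StructureClass.NOVEL_LONG_DSRNA
    return StructureClass.STRUCTURED_RNA
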