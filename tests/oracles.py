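"""Independent reference implementations used to validate the package.

These deliberately use different formulations from the library code:
exhaustive enumeration and top-down memoized recursion instead of the
iterative DP, and explicit chain enumeration instead of the successor DP.
"""

from __future__ import annotations

import statistics
from functools import lru_cache

import numpy as np

from dsrnascan.structure_curation import StemReport, pair_table


# --- boundary grouping --------------------------------------------------------------


def admissible(seg, radius: int) -> bool:
    if any(b - a > radius for a, b in zip(seg, seg[1:])):
        return False
    med = statistics.median(seg)
    return (seg[-1] - med) < radius and (med - seg[0]) < radius


def exhaustive_coarsest_partition(positions, radius=100):
    """Enumerate every contiguous partition; minimal group count, ties by
    longest-first-group lexicographic order. Exponential — small inputs only."""
    pos = tuple(sorted(positions))
    n = len(pos)
    found = []

    def rec(i, acc):
        if i == n:
            found.append(tuple(acc))
            return
        for j in range(n, i, -1):
            if admissible(pos[i:j], radius):
                rec(j, acc + [pos[i:j]])

    rec(0, [])
    return min(found, key=lambda part: (len(part), tuple(-len(g) for g in part)))


def memo_coarsest_partition(positions, radius=100):
    """Top-down memoized minimal partition with the same tie-break; handles
    a few hundred positions."""
    pos = tuple(sorted(positions))
    n = len(pos)

    @lru_cache(maxsize=None)
    def f(i):
        if i == n:
            return 0, ()
        options = []
        for j in range(i + 1, n + 1):
            if pos[j - 1] - pos[i] >= 2 * radius:
                break
            seg = pos[i:j]
            if admissible(seg, radius):
                cnt, rest = f(j)
                options.append((1 + cnt, -len(seg), (seg,) + rest))
        best = min(options)
        return best[0], best[2]

    return f(0)[1]


def random_grouping_instance(rng: np.random.Generator, max_positions=30):
    """Clustered coordinates like real skip boundaries."""
    pos = []
    for _ in range(int(rng.integers(1, 6))):
        center = int(rng.integers(0, 4000))
        m = int(rng.integers(1, 9))
        sd = float(rng.uniform(3, 120))
        pos.extend(int(round(x)) for x in rng.normal(center, sd, m))
    return sorted(pos[:max_positions])


# --- duplex stem --------------------------------------------------------------------


def exhaustive_stem_report(dotbracket: str, tolerance: int = 30) -> StemReport:
    """Enumerate every helix chain explicitly; best by (pairs, outermost)."""
    partner = pair_table(dotbracket)
    pairs = sorted((i, j) for i, j in enumerate(partner) if j > i)
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and p == (helices[-1][-1][0] + 1, helices[-1][-1][1] - 1):
            helices[-1].append(p)
        else:
            helices.append([p])
    if not helices:
        return StemReport(0, 0.0)
    chains: list[list[int]] = []

    def extend(chain):
        chains.append(chain)
        a, b = helices[chain[-1]][-1]
        for m in range(chain[-1] + 1, len(helices)):
            c, d = helices[m][0]
            if a < c and d < b and c - a - 1 <= tolerance and b - d - 1 <= tolerance:
                extend(chain + [m])

    for k in range(len(helices)):
        extend([k])
    best = None
    for chain in chains:
        length = sum(len(helices[k]) for k in chain)
        oi, oj = helices[chain[0]][0]
        ii, ij = helices[chain[-1]][-1]
        span = (ii - oi + 1) + (oj - ij + 1)
        key = (length, -chain[0])
        if best is None or key > best[0]:
            best = (key, StemReport(length, (span - 2 * length) / span))
    return best[1]


# --- flat per-window feature recomputation ------------------------------------------


def brute_force_features(window, reads, genome, min_skip_length=20, radius=100):
    """Recompute all 38 features with flat loops; returns a dict by name."""
    from dsrnascan.feature_extraction import DINUCLEOTIDES

    overlapping = [
        r for r in reads if r.aln_start < window.end and r.aln_end > window.start
    ]
    events = [
        s
        for r in overlapping
        for s in r.skips
        if s.length >= min_skip_length and window.start <= s.start < window.end
    ]
    skipping = sum(
        1
        for r in overlapping
        if any(
            s.length >= min_skip_length and window.start <= s.start < window.end
            for s in r.skips
        )
    )
    out = {
        "skip_ratio": skipping / len(overlapping),
        "len_skip": sum(s.length for s in events) / len(events),
    }
    start_groups = memo_coarsest_partition([s.start for s in events], radius)
    end_groups = memo_coarsest_partition([s.end for s in events], radius)
    out["group_num"] = (len(start_groups) + len(end_groups)) / 2
    out["std_start"] = float(np.mean([np.std(g) for g in start_groups]))
    out["std_end"] = float(np.mean([np.std(g) for g in end_groups]))
    seqs = [genome[window.chrom][s.start : s.end] for s in events]
    out["gc_skip"] = float(
        np.mean([sum(b in "GC" for b in q) / len(q) for q in seqs])
    )
    starts = [q[:2] for q in seqs if set(q[:2]) <= set("ACGT")]
    ends = [q[-2:] for q in seqs if set(q[-2:]) <= set("ACGT")]
    for d in DINUCLEOTIDES:
        out[f"bp_start_{d}"] = starts.count(d) / len(starts) if starts else 0.0
        out[f"bp_end_{d}"] = ends.count(d) / len(ends) if ends else 0.0
    return out
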