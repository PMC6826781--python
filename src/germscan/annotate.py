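"""Structural annotation of repeat families: tandem core units, inverted
cassettes, scaffold assignment and centromeric-candidate ranking.

The core unit of a tandem repeat is detected alignment-free: for each
candidate period p, the self-match fraction under shift p (share of
positions i with base(i) == base(i+p)) is computed and the smallest
period scoring at least ``min_score`` is reported with a column-majority
consensus.  Inverted cassettes (blocks of tandem units duplicated in
reverse complement) are found by locally aligning a sequence to its own
reverse complement.  Repeats are assigned to the genomic scaffold with
the most qualifying hits (>= 80% of repeat bases aligned), and repeats
are ranked by mean somatic read depth to nominate centromeric
(somatically abundant) candidates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .assembly import RepeatConsensus
from .enrich import CoverageProfile
from .errors import ParameterError
from .merge import MergeParams, alignment_sequence, local_align
from .seqs import revcomp

_MIN_OVERLAP = 12  # minimum compared positions for a period to be considered


@dataclass
class TandemAnnotation:
    sequence_id: str
    core_unit_length: int | None
    core_consensus: str | None
    periodicity_score: float
    array_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    inverted_cassettes: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list
    )


@dataclass
class ScaffoldAssignment:
    repeat_id: str
    scaffold_id: str | None
    hit_count: int
    fraction_bases_aligned: float


def _self_match_score(codes: np.ndarray, p: int) -> tuple[float, int]:
    n = codes.size - p
    if n <= 0:
        return 0.0, 0
    m = int((codes[:-p] == codes[p:]).sum())
    return m / n, n


def detect_core_unit(
    sequence: str,
    period_range: tuple[int, int] = (5, 200),
    min_score: float = 0.8,
    sequence_id: str = "",
) -> TandemAnnotation:
    """Detect the tandem core unit of a sequence by shift self-identity.

    Scans periods from ``period_range[0]`` upward and reports the
    smallest qualifying period (an automated convention: a perfect array
    also qualifies at every multiple of the true unit).  A refinement
    pass keeps the best-scoring period within +-2 bp of the first
    qualifier.  When no period qualifies, ``core_unit_length`` is None
    and ``periodicity_score`` is the maximum observed.
    """
    pmin, pmax = period_range
    if len(sequence) < 2 * pmin:
        raise ParameterError("sequence shorter than twice the minimum period")
    from .seqs import encode

    codes = encode(sequence.upper())
    hi = min(pmax, len(sequence) - _MIN_OVERLAP)
    best_p, best_s = None, 0.0
    for p in range(pmin, hi + 1):
        s, n = _self_match_score(codes, p)
        if n < _MIN_OVERLAP:
            break
        if s > best_s:
            best_s = s
        if s >= min_score:
            best_p = p
            break
    if best_p is None:
        return TandemAnnotation(sequence_id, None, None, best_s)
    # refinement: the true period of an indel-disrupted array may sit
    # within a couple of bases of the first qualifier
    cand = []
    for p in range(max(pmin, best_p - 2), min(hi, best_p + 2) + 1):
        s, n = _self_match_score(codes, p)
        if n >= _MIN_OVERLAP:
            cand.append((s, -p))
    score, negp = max(cand)
    p = -negp
    consensus = "".join(
        Counter(sequence[i::p]).most_common(1)[0][0] for i in range(p)
    )
    intervals = _periodic_runs(codes, p, min_score)
    return TandemAnnotation(
        sequence_id,
        p,
        consensus,
        score,
        array_intervals=intervals,
    )


def _periodic_runs(codes: np.ndarray, p: int, min_score: float):
    """Maximal intervals where the shift-p self-match holds locally."""
    n = codes.size
    m = (codes[:-p] == codes[p:]).astype(np.float64)
    w = min(max(p, 8), m.size)
    kernel = np.ones(w) / w
    smooth = np.convolve(m, kernel, mode="same")
    ok = smooth >= min_score
    intervals = []
    i = 0
    while i < ok.size:
        if ok[i]:
            j = i
            while j < ok.size and ok[j]:
                j += 1
            intervals.append((i, min(n, j + p), "+"))
            i = j
        else:
            i += 1
    return intervals


def find_inverted_cassettes(
    sequence: str,
    min_cassette: int = 100,
    identity_threshold: float = 0.8,
    params: MergeParams | None = None,
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Pairs of disjoint intervals where one is the reverse complement of
    the other (identity >= 0.8, length >= min_cassette)."""
    params = params or MergeParams()
    if min_cassette < params.seed_word_size:
        raise ParameterError("min_cassette must be >= the seed word size")
    n = len(sequence)
    if n < 2 * min_cassette:
        return []
    hits = local_align(sequence, revcomp(sequence), params, strands="+")
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    for h in hits:
        if h.identity < identity_threshold:
            continue
        a = (h.query_start, h.query_end)
        b = (n - h.subject_end, n - h.subject_start)
        if a[0] > b[0]:
            a, b = b, a
        if a[1] > b[0]:
            # a self-overlapping hit is a palindrome: query position i pairs
            # with position 2c - i around the centre c; split it there
            c = (a[0] + b[1]) // 2
            a, b = (a[0], c), (c, b[1])
        if min(a[1] - a[0], b[1] - b[0]) < min_cassette:
            continue
        dup = False
        for pa, pb in pairs:
            if _frac_overlap(a, pa) >= 0.8 and _frac_overlap(b, pb) >= 0.8:
                dup = True
                break
        if not dup:
            pairs.append((a, b))
    pairs.sort()
    return pairs


def _frac_overlap(x: tuple[int, int], y: tuple[int, int]) -> float:
    ov = max(0, min(x[1], y[1]) - max(x[0], y[0]))
    shorter = min(x[1] - x[0], y[1] - y[0])
    return ov / shorter if shorter > 0 else 0.0


def assign_scaffold(
    repeat: RepeatConsensus,
    scaffolds: list[tuple[str, str]],
    min_fraction: float = 0.80,
    params: MergeParams | None = None,
) -> ScaffoldAssignment:
    """Assign a repeat to the scaffold with the most qualifying hits.

    A hit qualifies when it covers >= ``min_fraction`` of the repeat's
    bases; ties between scaffolds break toward the greater summed hit
    score.  Scanning order is sorted by scaffold id, so the result does
    not depend on input order.
    """
    if not scaffolds:
        raise ParameterError("scaffold set is empty")
    params = params or MergeParams(max_extensions=3000)
    query = alignment_sequence(repeat)
    qlen = len(repeat.sequence)
    best = None  # (hits, total_score, scaffold_id, best_fraction)
    for sid, seq in sorted(scaffolds):
        hits = local_align(query, seq, params, query_id=repeat.id, subject_id=sid)
        good = [
            h
            for h in hits
            if min(1.0, (h.query_end - h.query_start) / qlen) >= min_fraction
        ]
        if not good:
            continue
        total = sum(h.score for h in good)
        frac = max(min(1.0, (h.query_end - h.query_start) / qlen) for h in good)
        key = (len(good), total)
        if best is None or key > (best[0], best[1]):
            best = (len(good), total, sid, frac)
    if best is None:
        return ScaffoldAssignment(repeat.id, None, 0, 0.0)
    return ScaffoldAssignment(repeat.id, best[2], best[0], best[3])


def rank_by_somatic_coverage(
    library: list[RepeatConsensus],
    somatic_profiles: dict[str, CoverageProfile],
    top_n: int = 3,
) -> list[tuple[str, float]]:
    """Repeats ordered by mean somatic depth descending (ties: id lexicographic).

    The top entries nominate centromeric candidates: satellites shared by
    both tissues at the highest somatic copy number.
    """
    rows = []
    for rec in library:
        prof = somatic_profiles.get(rec.id)
        depth = prof.mean_depth if prof is not None else 0.0
        rows.append((rec.id, float(depth)))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return rows[:top_n]
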