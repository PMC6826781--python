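"""Per-base coverage, interval scanning, enrichment scoring and the germline filter.

Reads from each tissue are placed on the repeat library by canonical
k-mer seeds: a read's leftmost seed present in the library decides its
single best placement (ties go to the leftmost position on the
lexicographically smallest sequence id), and depth is incremented over
the read's aligned bases.  Tandem consensus sequences are mapped as
circles of their core unit so that read bases are never lost to
end-clipping on a consensus much shorter than the read.

Coverage is then scanned into intervals of at least ``v`` eligible bases
(a base is eligible when either tissue covers it at the minimum depth;
depths above the caps are truncated), each interval is scored as
log2(standardized germline coverage / standardized somatic coverage)
using the modal depth of each sample as the standardizer, genomic span
is estimated as sequence length x (depth / modal depth), and candidates
are kept when score > 5 and span > 40 kb (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EstimationError, ParameterError
from . import seqs


@dataclass
class MapSeq:
    """A mapping target: a library sequence, optionally circularized.

    ``circular`` targets hold the core tandem unit; reads wrap modulo its
    length so every read base lands on the unit.
    """

    seq_id: str
    sequence: str
    circular: bool = False


@dataclass
class CoverageProfile:
    sequence_id: str
    depth: np.ndarray
    modal_depth: float | None = None

    @property
    def length(self) -> int:
        return int(self.depth.size)

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0


class MappingIndex:
    """Canonical k-mer index over an ordered set of mapping targets.

    Each canonical k-mer keeps only its first occurrence, which makes
    placement deterministic and identical across samples.  Circular
    (tandem-unit) targets take priority over linear ones, and shorter
    units beat longer ones (the smallest period is the elementary
    satellite monomer; longer circular targets sharing its k-mers are
    composite unit+variant loops), so that reads from a satellite family
    land on its elementary circularized unit rather than on a variant
    fragment sharing the same k-mers.  Remaining ties go to the
    lexicographically smallest sequence id, then the leftmost position.
    """

    def __init__(self, targets: list[MapSeq], k: int = 31):
        if not targets:
            raise ParameterError("mapping reference is empty")
        self.k = k
        self.targets = sorted(
            targets,
            key=lambda t: (not t.circular, len(t.sequence) if t.circular else 0, t.seq_id),
        )
        vals_all, seq_all, pos_all, fwd_all = [], [], [], []
        for si, t in enumerate(self.targets):
            seq = t.sequence.upper()
            n = len(seq)
            if t.circular:
                reps = -(-(n + k - 1) // n)  # enough copies for windows at 0..n-1
                ext = (seq * reps)[: n + k - 1]
                limit = n
            else:
                ext = seq
                limit = max(0, n - k + 1)
            if limit == 0:
                continue
            codes = seqs.encode(ext)
            pos, vals = seqs.kmer_values(codes, k)
            keep = pos < limit
            pos, vals = pos[keep], vals[keep]
            canon = seqs.canonical_values(vals, k)
            vals_all.append(canon)
            seq_all.append(np.full(pos.size, si, dtype=np.int32))
            pos_all.append(pos.astype(np.int32))
            fwd_all.append(vals == canon)
        if not vals_all:
            raise ParameterError("no sequence in the reference is as long as k")
        vals = np.concatenate(vals_all)
        seq_i = np.concatenate(seq_all)
        pos_i = np.concatenate(pos_all)
        fwd_i = np.concatenate(fwd_all)
        uniq, first = np.unique(vals, return_index=True)
        self.kmer_values = uniq
        self.kmer_seq = seq_i[first]
        self.kmer_pos = pos_i[first]
        self.kmer_fwd = fwd_i[first]
        self.lengths = np.array([len(t.sequence) for t in self.targets], dtype=np.int64)


class _MapState:
    def __init__(self, index: MappingIndex):
        self.index = index
        self.diffs = [np.zeros(int(n) + 1, dtype=np.int64) for n in index.lengths]
        self.wraps = np.zeros(len(index.targets), dtype=np.int64)
        self.unplaced = 0

    def place_batch(self, ridx, offset, canon, is_fwd, lens) -> None:
        index = self.index
        n_reads = lens.size
        if canon.size == 0:
            self.unplaced += n_reads
            return
        loc = np.searchsorted(index.kmer_values, canon)
        loc_clip = np.minimum(loc, index.kmer_values.size - 1)
        matched = index.kmer_values[loc_clip] == canon
        if not matched.any():
            self.unplaced += n_reads
            return
        m_ridx = ridx[matched]
        # windows arrive ordered by (read, offset): the first window of
        # each read is the read's leftmost matching seed
        first_idx = np.concatenate(([0], np.flatnonzero(np.diff(m_ridx)) + 1))
        sel_reads = m_ridx[first_idx]
        self.unplaced += n_reads - sel_reads.size
        mloc = loc_clip[matched][first_idx]
        moff = offset[matched][first_idx]
        mfwd = is_fwd[matched][first_idx]
        L = lens[sel_reads]
        tseq = index.kmer_seq[mloc]
        tpos = index.kmer_pos[mloc].astype(np.int64)
        same = index.kmer_fwd[mloc] == mfwd
        start = np.where(same, tpos - moff, tpos - (L - index.k - moff))
        for si in np.unique(tseq):
            sel = tseq == si
            s, l = start[sel], L[sel]
            n = int(index.lengths[si])
            d = self.diffs[si]
            if index.targets[si].circular:
                t = np.mod(s, n)
                self.wraps[si] += int((l // n).sum())
                rem = l % n
                end1 = np.minimum(t + rem, n)
                np.add.at(d, t, 1)
                np.add.at(d, end1, -1)
                over = t + rem - n
                has = over > 0
                if has.any():
                    d[0] += int(has.sum())
                    np.add.at(d, over[has], -1)
            else:
                s0 = np.clip(s, 0, n)
                s1 = np.clip(s + l, 0, n)
                np.add.at(d, s0, 1)
                np.add.at(d, s1, -1)

    def profiles(self) -> dict[str, CoverageProfile]:
        out = {}
        for si, t in enumerate(self.index.targets):
            depth = np.cumsum(self.diffs[si][:-1]) + self.wraps[si]
            out[t.seq_id] = CoverageProfile(t.seq_id, depth)
        return out


def map_coverage(
    reads,
    indices: list[MappingIndex],
    seed_stride: int = 1,
    batch_size: int = 200_000,
) -> list[tuple[dict[str, CoverageProfile], int]]:
    """Place one read set on several references in a single pass.

    All indices must share one k.  ``seed_stride`` subsamples candidate
    seed windows (offsets 0, stride, 2*stride, ...) to cut lookup cost;
    placement still uses the leftmost matching sampled seed.
    """
    ks = {ix.k for ix in indices}
    if len(ks) != 1:
        raise ParameterError("all mapping indices must share one k")
    k = ks.pop()
    states = [_MapState(ix) for ix in indices]

    from .kmers import _iter_sequences

    for batch in _iter_sequences(reads, batch_size):
        ridx, offset, canon, is_fwd = seqs.batch_kmers(batch, k)
        lens = np.fromiter((len(s) for s in batch), dtype=np.int64, count=len(batch))
        if seed_stride > 1 and offset.size:
            keep = offset % seed_stride == 0
            ridx, offset, canon, is_fwd = ridx[keep], offset[keep], canon[keep], is_fwd[keep]
        for st in states:
            st.place_batch(ridx, offset, canon, is_fwd, lens)
    return [(st.profiles(), st.unplaced) for st in states]


def compute_coverage(
    reads,
    reference: list[MapSeq] | MappingIndex,
    k: int = 31,
    seed_stride: int = 1,
    batch_size: int = 200_000,
) -> tuple[dict[str, CoverageProfile], int]:
    """Best-seed placement coverage of a read set over a reference.

    ``reads``: FASTQ path(s) or an iterable of sequence strings.  Returns
    ({seq_id: CoverageProfile}, number of unplaced reads).
    """
    index = reference if isinstance(reference, MappingIndex) else MappingIndex(reference, k)
    return map_coverage(reads, [index], seed_stride, batch_size)[0]


def modal_depth(profiles, min_depth: float = 1.0) -> int:
    """Mode of the pooled per-base depth histogram over bases >= min_depth.

    Ties break toward the larger depth, mirroring the k-mer-spectrum
    mode rule.
    """
    if isinstance(profiles, dict):
        profiles = profiles.values()
    arrays = [p.depth for p in profiles]
    if not arrays:
        raise EstimationError("no coverage profiles")
    pooled = np.concatenate(arrays)
    pooled = pooled[pooled >= min_depth]
    if pooled.size == 0:
        raise EstimationError(f"no bases with depth >= {min_depth}")
    counts = np.bincount(pooled.astype(np.int64))
    best = int(np.flatnonzero(counts == counts.max())[-1])
    return best


# ---------------------------------------------------------------------------
# interval scanning and scoring


@dataclass
class EnrichmentParams:
    min_interval_span: int = 5000        # v: close an interval at this many eligible bases
    report_min_length: int = 0           # l: minimum eligible length of a trailing interval
    min_depth_1: float = 10.0            # a
    min_depth_2: float = 10.0            # b
    max_depth_1: float = 12_000_000.0    # A
    max_depth_2: float = 12_000_000.0    # B

    def __post_init__(self) -> None:
        if not self.min_interval_span >= self.report_min_length >= 0:
            raise ParameterError("need v >= l >= 0")
        if self.max_depth_1 < self.min_depth_1 or self.max_depth_2 < self.min_depth_2:
            raise ParameterError("depth caps must be >= depth minima")


@dataclass
class EnrichmentInterval:
    sequence_id: str
    start: int
    end: int
    n_eligible: int
    mean_depth_1: float
    mean_depth_2: float
    mean_ratio: float                 # mean over eligible bases of d1/max(d2, 1)
    enrichment_score: float | None = None
    estimated_span: float | None = None


@dataclass
class FilterParams:
    min_score: float = 5.0
    min_span: float = 40_000.0

    def __post_init__(self) -> None:
        if self.min_score <= 0 or self.min_span <= 0:
            raise ParameterError("filter thresholds must be > 0")


def scan_intervals(
    profiles1: dict[str, CoverageProfile],
    profiles2: dict[str, CoverageProfile],
    params: EnrichmentParams | None = None,
) -> list[EnrichmentInterval]:
    """Split each sequence's eligible bases into intervals of >= v bases.

    A base is eligible when depth1 >= a OR depth2 >= b; capped depths
    above A/B contribute the cap.  Eligible bases are accumulated left to
    right and an interval closes once v have been collected; a trailing
    interval with fewer is reported when its eligible length >= l.
    Interval means are over eligible bases only.
    """
    params = params or EnrichmentParams()
    if set(profiles1) != set(profiles2):
        raise ParameterError("the two samples cover different sequence sets")
    out: list[EnrichmentInterval] = []
    for sid in sorted(profiles1):
        d1 = profiles1[sid].depth.astype(np.float64)
        d2 = profiles2[sid].depth.astype(np.float64)
        if d1.size != d2.size:
            raise ParameterError(f"{sid}: profile lengths differ between samples")
        eligible = (d1 >= params.min_depth_1) | (d2 >= params.min_depth_2)
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            continue
        c1 = np.minimum(d1, params.max_depth_1)[idx]
        c2 = np.minimum(d2, params.max_depth_2)[idx]
        ratio = c1 / np.maximum(c2, 1.0)
        v = params.min_interval_span
        n_full, tail = divmod(idx.size, v)
        bounds = [(i * v, (i + 1) * v) for i in range(n_full)]
        if tail and tail >= params.report_min_length:
            bounds.append((n_full * v, idx.size))
        for lo, hi in bounds:
            block = idx[lo:hi]
            out.append(
                EnrichmentInterval(
                    sequence_id=sid,
                    start=int(block[0]),
                    end=int(block[-1]) + 1,
                    n_eligible=hi - lo,
                    mean_depth_1=float(c1[lo:hi].mean()),
                    mean_depth_2=float(c2[lo:hi].mean()),
                    mean_ratio=float(ratio[lo:hi].mean()),
                )
            )
    return out


def enrichment_score(
    mean1: float,
    mean2: float,
    modal1: float,
    modal2: float,
    floor: float = 1.0,
) -> float:
    """log2((mean1/modal1) / (max(mean2, floor)/modal2)); finite by the floor rule."""
    if modal1 <= 0 or modal2 <= 0:
        raise ParameterError("modal depths must be > 0")
    num = mean1 / modal1
    den = max(mean2, floor) / modal2
    if num <= 0:
        return float("-inf")
    return float(np.log2(num / den))


def estimate_span(sequence_length: float, mean_sample1_depth: float, modal1: float) -> float:
    """Genomic span: sequence length x (sample-1 depth / modal sample-1 depth)."""
    if modal1 <= 0:
        raise ParameterError("modal depth must be > 0")
    return float(sequence_length) * (float(mean_sample1_depth) / float(modal1))


def score_intervals(
    intervals: list[EnrichmentInterval],
    seq_lengths: dict[str, int],
    modal1: float,
    modal2: float,
    floor: float = 1.0,
    estimator: str = "ratio_of_means",
) -> list[EnrichmentInterval]:
    """Attach enrichment score and estimated span to each interval.

    ``estimator`` selects the per-interval fold-change estimator:
    "ratio_of_means" (default) uses the interval's mean depths;
    "mean_of_ratios" averages per-base depth ratios instead.
    """
    for iv in intervals:
        if estimator == "ratio_of_means":
            iv.enrichment_score = enrichment_score(
                iv.mean_depth_1, iv.mean_depth_2, modal1, modal2, floor
            )
        elif estimator == "mean_of_ratios":
            iv.enrichment_score = (
                float(np.log2(iv.mean_ratio * modal2 / modal1))
                if iv.mean_ratio > 0
                else float("-inf")
            )
        else:
            raise ParameterError(f"unknown estimator: {estimator}")
        iv.estimated_span = estimate_span(
            seq_lengths[iv.sequence_id], iv.mean_depth_1, modal1
        )
    return intervals


def filter_germline(
    intervals: list[EnrichmentInterval],
    params: FilterParams | None = None,
) -> list[EnrichmentInterval]:
    """Keep intervals with score > min_score AND span > min_span (strict), in order."""
    params = params or FilterParams()
    out = []
    for iv in intervals:
        if iv.enrichment_score is None or iv.estimated_span is None:
            raise ParameterError("intervals must be scored before filtering")
        if iv.enrichment_score > params.min_score and iv.estimated_span > params.min_span:
            out.append(iv)
    return out


# ---------------------------------------------------------------------------
# bedGraph io


def write_bedgraph(profiles: dict[str, CoverageProfile], path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(profiles):
            depth = profiles[sid].depth
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depth.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{sid}\t{s}\t{e}\t{int(depth[s])}\n")


def read_bedgraph(path, seq_lengths: dict[str, int]) -> dict[str, CoverageProfile]:
    profiles = {
        sid: CoverageProfile(sid, np.zeros(n, dtype=np.int64))
        for sid, n in seq_lengths.items()
    }
    with open(path) as fh:
        for line in fh:
            sid, s, e, d = line.split()
            if sid in profiles:
                profiles[sid].depth[int(s) : int(e)] = int(float(d))
    return profiles
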