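"""Seeded local alignment and identity-based repeat-library merging.

De novo consensus sequences are reconciled with a reference-derived
repeat library (a de novo sequence aligning to a reference repeat at
>90% identity over >80% of its own length is replaced by the longer
reference sequence) and screened against known repeats (sequences
matching a known repeat at >=99% identity are excluded, with the known
sequence itself appended once).

Alignment is seed-and-extend: exact word matches (word size 11, both
strands) are clustered by diagonal and each cluster is extended by local
Smith-Waterman (Bio.Align.PairwiseAligner) on a padded window.  Cyclic
consensus sequences are doubled before alignment so any rotation of the
same tandem unit can match; fractions are computed against the original
length.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .assembly import RepeatConsensus
from .errors import InputError, ParameterError
from .seqs import revcomp


@dataclass
class MergeParams:
    replace_identity: float = 0.90
    replace_coverage: float = 0.80
    known_identity: float = 0.99
    seed_word_size: int = 11
    match_score: float = 1.0
    mismatch_score: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    max_diag_spread: int = 20   # diagonal tolerance when clustering seeds
    max_seed_gap: int = 60      # max unseeded stretch inside one cluster
    pad: int = 15               # extension window padding
    max_extensions: int = 0     # cap on extended seed clusters per strand (0 = all)

    def __post_init__(self) -> None:
        for name in ("replace_identity", "replace_coverage", "known_identity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ParameterError(f"{name} must be in (0, 1]")
        if self.seed_word_size < 4:
            raise ParameterError("seed_word_size too small")


@dataclass
class AlignmentHit:
    """One merged local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    identity: float          # matches / alignment columns (gaps are columns)
    aligned_query_fraction: float
    score: float
    strand: str              # "+" or "-"
    length: int              # alignment columns

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def subject_span(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)


def _aligner(params: MergeParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = params.match_score
    a.mismatch_score = params.mismatch_score
    a.open_gap_score = params.gap_open
    a.extend_gap_score = params.gap_extend
    return a


def _word_index(seq: str, w: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        if "N" in word:
            continue
        index.setdefault(word, []).append(i)
    return index


def _seed_matches(query: str, index: dict[str, list[int]], w: int):
    out = []
    for i in range(len(query) - w + 1):
        hits = index.get(query[i : i + w])
        if hits:
            for j in hits:
                out.append((i, j))
    return out


def _cluster_seeds(matches, params: MergeParams):
    matches.sort(key=lambda m: (m[1] - m[0], m[0]))
    clusters = []
    cur = []
    for qpos, spos in matches:
        diag = spos - qpos
        if cur and (
            diag - (cur[-1][1] - cur[-1][0]) > params.max_diag_spread
            or qpos - cur[-1][0] > params.max_seed_gap
        ):
            clusters.append(cur)
            cur = []
        cur.append((qpos, spos))
    if cur:
        clusters.append(cur)
    return clusters


def _alignment_stats(alignment, qseq: str, sseq: str):
    blocks_q, blocks_s = alignment.aligned
    matches = 0
    aligned_pairs = 0
    columns = 0
    prev_q = prev_s = None
    for (q0, q1), (s0, s1) in zip(blocks_q, blocks_s):
        if prev_q is not None:
            columns += (q0 - prev_q) + (s0 - prev_s)
        for a, b in zip(qseq[q0:q1], sseq[s0:s1]):
            if a == b:
                matches += 1
        aligned_pairs += q1 - q0
        columns += q1 - q0
        prev_q, prev_s = q1, s1
    q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s_start, s_end = int(blocks_s[0][0]), int(blocks_s[-1][1])
    return matches, columns, (q_start, q_end), (s_start, s_end)


def local_align(
    query: str,
    subject: str,
    params: MergeParams | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
    strands: str = "+-",
) -> list[AlignmentHit]:
    """Seeded local alignment of query against subject.

    Returns merged hits sorted by score descending.  Hit coordinates are
    0-based half-open on the forward orientation of both input strings;
    a "-" strand hit means the reverse complement of the query aligned.
    ``strands`` restricts the search (a self-vs-reverse-complement scan
    uses "+" only, as its "-" strand is the trivial self-identity).
    """
    if not query or not subject:
        raise ParameterError("query and subject must be non-empty")
    params = params or MergeParams()
    w = params.seed_word_size
    aligner = _aligner(params)
    index = _word_index(subject, w)
    qlen = len(query)
    hits: list[AlignmentHit] = []
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        matches = _seed_matches(q, index, w)
        clusters = _cluster_seeds(matches, params)
        if params.max_extensions and len(clusters) > params.max_extensions:
            # largest seed clusters first; keeps the strongest candidate hits
            clusters = sorted(clusters, key=len, reverse=True)[: params.max_extensions]
        for cluster in clusters:
            qlo = max(0, min(m[0] for m in cluster) - params.pad)
            qhi = min(len(q), max(m[0] for m in cluster) + w + params.pad)
            slo = max(0, min(m[1] for m in cluster) - params.pad)
            shi = min(len(subject), max(m[1] for m in cluster) + w + params.pad)
            qseq, sseq = q[qlo:qhi], subject[slo:shi]
            try:
                alignment = next(iter(aligner.align(qseq, sseq)))
            except StopIteration:  # no positive-score alignment
                continue
            if alignment.score <= 0 or len(alignment.aligned[0]) == 0:
                continue
            m, cols, (a0, a1), (b0, b1) = _alignment_stats(alignment, qseq, sseq)
            if cols == 0:
                continue
            q0, q1 = qlo + a0, qlo + a1
            if strand == "-":
                q0, q1 = qlen - (qlo + a1), qlen - (qlo + a0)
            hits.append(
                AlignmentHit(
                    query_id=query_id,
                    subject_id=subject_id,
                    query_start=q0,
                    query_end=q1,
                    subject_start=slo + b0,
                    subject_end=slo + b1,
                    identity=m / cols,
                    aligned_query_fraction=(a1 - a0) / qlen,
                    score=float(alignment.score),
                    strand=strand,
                    length=cols,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.query_start, h.subject_start))
    return _dedup_hits(hits)


def _overlap(a0, a1, b0, b1) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _dedup_hits(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits that duplicate a better hit on both query and subject."""
    kept: list[AlignmentHit] = []
    for h in hits:
        dup = False
        for g in kept:
            qo = _overlap(h.query_start, h.query_end, g.query_start, g.query_end)
            so = _overlap(h.subject_start, h.subject_end, g.subject_start, g.subject_end)
            qlen = min(h.query_end - h.query_start, g.query_end - g.query_start)
            slen = min(h.subject_end - h.subject_start, g.subject_end - g.subject_start)
            if qlen > 0 and slen > 0 and qo / qlen >= 0.5 and so / slen >= 0.5:
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def alignment_sequence(record: RepeatConsensus) -> str:
    """The sequence used in alignments: doubled when the consensus is cyclic."""
    return record.sequence * 2 if record.is_cyclic else record.sequence


def best_hit(
    query: RepeatConsensus,
    subject: RepeatConsensus,
    params: MergeParams | None = None,
) -> AlignmentHit | None:
    """Best local hit between two consensus records (rotation-aware)."""
    hits = local_align(
        alignment_sequence(query),
        alignment_sequence(subject),
        params,
        query_id=query.id,
        subject_id=subject.id,
    )
    if not hits:
        return None
    h = hits[0]
    # fractions are measured against the original (un-doubled) lengths
    h.aligned_query_fraction = min(1.0, (h.query_end - h.query_start) / len(query.sequence))
    return h


def _check_unique_ids(*libraries) -> None:
    """Reject id collisions, except a byte-identical record appearing in
    both libraries (a reference sequence adopted by a previous merge)."""
    seen: dict[str, str] = {}
    for lib in libraries:
        for rec in lib:
            if rec.id in seen and seen[rec.id] != rec.sequence:
                raise InputError(f"duplicate sequence id: {rec.id}")
            seen[rec.id] = rec.sequence


def merge_with_reference(
    denovo: list[RepeatConsensus],
    reference: list[RepeatConsensus],
    params: MergeParams | None = None,
) -> list[RepeatConsensus]:
    """Replace de novo sequences by matching, longer reference repeats.

    A de novo sequence with a hit of identity > ``replace_identity``
    covering > ``replace_coverage`` of its own length is replaced by the
    aligned reference sequence when the reference is longer; replacements
    are de-duplicated and unmatched sequences pass through unchanged.
    """
    params = params or MergeParams()
    _check_unique_ids(denovo, reference)
    ref_by_id = {r.id: r for r in reference}
    out: list[RepeatConsensus] = []
    used_refs: set[str] = set()
    for rec in denovo:
        if rec.id in ref_by_id and rec.sequence == ref_by_id[rec.id].sequence:
            # already adopted from the reference by a previous merge
            if rec.id not in used_refs:
                used_refs.add(rec.id)
                out.append(rec)
            continue
        replacement = None
        for ref in reference:
            if len(ref.sequence) <= len(rec.sequence):
                continue
            h = best_hit(rec, ref, params)
            if (
                h is not None
                and h.identity > params.replace_identity
                and h.aligned_query_fraction > params.replace_coverage
            ):
                if replacement is None or len(ref.sequence) > len(replacement.sequence):
                    replacement = ref
        if replacement is None:
            out.append(rec)
        elif replacement.id not in used_refs:
            used_refs.add(replacement.id)
            out.append(
                RepeatConsensus(
                    id=replacement.id,
                    sequence=replacement.sequence,
                    provenance="reference",
                    is_cyclic=replacement.is_cyclic,
                    member_kmer_count=rec.member_kmer_count,
                    cycle_core=replacement.cycle_core,
                )
            )
    return out


def exclude_known(
    library: list[RepeatConsensus],
    known: list[RepeatConsensus],
    identity_threshold: float = 0.99,
    min_fraction: float = 0.5,
    params: MergeParams | None = None,
) -> list[RepeatConsensus]:
    """Drop library sequences matching a known repeat; append the known set once.

    A qualifying match has identity >= ``identity_threshold`` over at
    least ``min_fraction`` of the library sequence, so short spurious
    seed-perfect matches do not trigger exclusion.
    """
    params = params or MergeParams()
    if not known:
        return list(library)
    out: list[RepeatConsensus] = []
    for rec in library:
        excluded = False
        for kn in known:
            h = best_hit(rec, kn, params)
            if (
                h is not None
                and h.identity >= identity_threshold
                and h.aligned_query_fraction >= min_fraction
            ):
                excluded = True
                break
        if not excluded:
            out.append(rec)
    present = {r.id for r in out}
    for kn in known:
        if kn.id not in present:
            out.append(
                RepeatConsensus(
                    id=kn.id,
                    sequence=kn.sequence,
                    provenance="known",
                    is_cyclic=kn.is_cyclic,
                    cycle_core=kn.cycle_core,
                )
            )
            present.add(kn.id)
    return out
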