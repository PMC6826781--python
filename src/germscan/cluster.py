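"""Greedy identity clustering of germline-enriched repeats into families.

Filtered candidate sequences are grouped CD-HIT-style: sorted by length
descending, each sequence joins the first cluster whose representative it
matches at >= 80% identity with the alignment covering >= 30% of both the
shorter and the longer sequence, else founds a new cluster.  Clusters are
then cross-aligned; pairs of clusters linked by at least four qualifying
hits are merged transitively (union-find).  Rotation of tandem units is
handled by doubling cyclic consensus sequences before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .assembly import RepeatConsensus
from .errors import InputError, ParameterError
from .merge import MergeParams, alignment_sequence, local_align


@dataclass
class ClusterParams:
    identity_threshold: float = 0.80
    min_coverage_shorter: float = 0.30   # aS
    min_coverage_longer: float = 0.30    # aL
    merge_min_hits: int = 4
    seed_word_size: int = 11
    min_hit_length: int = 50             # columns for a cross-merge hit to count
    best_fit: bool = False               # join the best-matching cluster, not the first
    hit_counting: str = "hsp"            # "hsp": each alignment; "pair": each sequence pair

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "min_coverage_shorter", "min_coverage_longer"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ParameterError(f"{name} must be in (0, 1]")
        if self.merge_min_hits < 1:
            raise ParameterError("merge_min_hits must be >= 1")
        if self.hit_counting not in ("hsp", "pair"):
            raise ParameterError("hit_counting must be 'hsp' or 'pair'")

    def merge_params(self) -> MergeParams:
        return MergeParams(seed_word_size=self.seed_word_size)


@dataclass
class RepeatCluster:
    cluster_id: str
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    combined_span: float = 0.0


def _match(
    query: RepeatConsensus,
    rep: RepeatConsensus,
    params: ClusterParams,
) -> float | None:
    """Identity of the best qualifying hit between query and representative,
    or None when no hit satisfies identity and both coverage fractions."""
    hits = local_align(
        alignment_sequence(query),
        alignment_sequence(rep),
        params.merge_params(),
        query_id=query.id,
        subject_id=rep.id,
    )
    qlen, slen = len(query.sequence), len(rep.sequence)
    short, long_ = min(qlen, slen), max(qlen, slen)
    best = None
    for h in hits:
        q_cov = min(1.0, (h.query_end - h.query_start) / qlen)
        s_cov = min(1.0, (h.subject_end - h.subject_start) / slen)
        cov_short = q_cov if qlen <= slen else s_cov
        cov_long = s_cov if qlen <= slen else q_cov
        if (
            h.identity >= params.identity_threshold
            and cov_short >= params.min_coverage_shorter
            and cov_long >= params.min_coverage_longer
        ):
            if best is None or h.identity > best:
                best = h.identity
    return best


def greedy_cluster(
    records: list[RepeatConsensus],
    spans: dict[str, float] | None = None,
    params: ClusterParams | None = None,
) -> list[RepeatCluster]:
    """Partition sequences into clusters by greedy incremental assignment."""
    params = params or ClusterParams()
    spans = spans or {}
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate sequence ids")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    clusters: list[RepeatCluster] = []
    reps: list[RepeatConsensus] = []
    for rec in ordered:
        chosen = None
        best_ident = -1.0
        for ci, rep in enumerate(reps):
            ident = _match(rec, rep, params)
            if ident is None:
                continue
            if not params.best_fit:
                chosen = ci
                break
            if ident > best_ident:
                best_ident, chosen = ident, ci
        if chosen is None:
            clusters.append(
                RepeatCluster(
                    cluster_id=f"cl{len(clusters) + 1:03d}",
                    representative_id=rec.id,
                    member_ids=[rec.id],
                    combined_span=float(spans.get(rec.id, 0.0)),
                )
            )
            reps.append(rec)
        else:
            clusters[chosen].member_ids.append(rec.id)
            clusters[chosen].combined_span += float(spans.get(rec.id, 0.0))
    return clusters


def _count_cross_hits(
    a: RepeatCluster,
    b: RepeatCluster,
    by_id: dict[str, RepeatConsensus],
    params: ClusterParams,
) -> int:
    n = 0
    for qa in a.member_ids:
        for qb in b.member_ids:
            hits = local_align(
                alignment_sequence(by_id[qa]),
                alignment_sequence(by_id[qb]),
                params.merge_params(),
                query_id=qa,
                subject_id=qb,
            )
            good = [
                h
                for h in hits
                if h.length >= params.min_hit_length
                and h.identity >= params.identity_threshold
            ]
            if params.hit_counting == "pair":
                n += 1 if good else 0
            else:
                n += len(good)
    return n


def cross_merge(
    clusters: list[RepeatCluster],
    records: list[RepeatConsensus],
    params: ClusterParams | None = None,
) -> list[RepeatCluster]:
    """Merge cluster pairs linked by >= merge_min_hits cross-alignment hits.

    Connectivity is transitive: connected components of the >=4-hit graph
    become single clusters whose representative is the longest member.
    """
    params = params or ClusterParams()
    by_id = {r.id: r for r in records}
    parent = list(range(len(clusters)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if find(i) == find(j):
                continue
            if _count_cross_hits(clusters[i], clusters[j], by_id, params) >= params.merge_min_hits:
                parent[find(j)] = find(i)

    groups: dict[int, list[int]] = {}
    for i in range(len(clusters)):
        groups.setdefault(find(i), []).append(i)
    merged: list[RepeatCluster] = []
    for root in sorted(groups):
        members: list[str] = []
        span = 0.0
        for ci in groups[root]:
            members.extend(clusters[ci].member_ids)
            span += clusters[ci].combined_span
        rep = max(members, key=lambda m: (len(by_id[m].sequence), m))
        merged.append(
            RepeatCluster(
                cluster_id=f"cl{len(merged) + 1:03d}",
                representative_id=rep,
                member_ids=members,
                combined_span=span,
            )
        )
    return merged


def cluster_report(
    clusters: list[RepeatCluster],
    records: list[RepeatConsensus] | None = None,
) -> pd.DataFrame:
    """Per-cluster table ordered by combined span descending."""
    rows = [
        dict(
            cluster_id=c.cluster_id,
            representative_id=c.representative_id,
            n_members=len(c.member_ids),
            member_ids=",".join(c.member_ids),
            combined_span=c.combined_span,
            singleton=len(c.member_ids) == 1,
        )
        for c in clusters
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["combined_span", "cluster_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df
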