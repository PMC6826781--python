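"""De novo assembly of abundant k-mers into repeat consensus sequences.

Abundant 31-mers are threaded onto a bidirected de Bruijn graph with a
smaller node size (29), where tandem satellite units appear as cycles: a
unit of period p induces exactly p node k-mers chained into a loop.
Maximal non-branching paths are compressed to linear consensus
sequences; pure cycles are linearized once (cut at the lexicographically
smallest node, with node_k-1 wraparound bases appended) and flagged
cyclic.  No bubble popping or tip clipping is attempted: the input is
already noise-thresholded, and branch counts are logged for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ParameterError
from .seqs import canonical_kmer, revcomp

log = logging.getLogger(__name__)

State = tuple[str, int]  # (canonical node, orientation +1/-1)


def _oriented(node: str, orient: int) -> str:
    return node if orient > 0 else revcomp(node)


def _rev(state: State) -> State:
    return (state[0], -state[1])


@dataclass
class DeBruijnGraph:
    """Bidirected de Bruijn graph over canonical node_k-mers."""

    node_k: int
    nodes: set[str] = field(default_factory=set)
    succ: dict[State, list[State]] = field(default_factory=dict)
    multiplicity: dict[str, int] = field(default_factory=dict)
    node_count: dict[str, int] = field(default_factory=dict)

    def successors(self, state: State) -> list[State]:
        return self.succ.get(state, [])

    def out_degree(self, state: State) -> int:
        return len(self.succ.get(state, []))

    def in_degree(self, state: State) -> int:
        return len(self.succ.get(_rev(state), []))

    @property
    def n_edges(self) -> int:
        """Undirected edge count (each edge is stored in both directions)."""
        return sum(len(v) for v in self.succ.values()) // 2


@dataclass
class RepeatConsensus:
    """One assembled / merged repeat sequence with provenance."""

    id: str
    sequence: str
    provenance: str = "denovo"  # denovo | reference | known
    is_cyclic: bool = False
    member_kmer_count: int = 0
    cycle_core: int | None = None  # tandem period of a linearized cycle

    def __len__(self) -> int:
        return len(self.sequence)


def build_graph(
    abundant_kmers,
    node_k: int = 29,
    counts: dict[str, int] | None = None,
) -> DeBruijnGraph:
    """Thread abundant k-mers onto a bidirected graph of node_k-mers.

    Nodes are the canonical node_k windows of every input k-mer; two
    oriented nodes are joined whenever one's (node_k-1)-suffix equals the
    other's (node_k-1)-prefix, which yields both the chains inside each
    input k-mer and the junctions between k-mers that overlap.  When
    per-k-mer ``counts`` are supplied, each node records the maximum
    count of the k-mers covering it (used by the relative coverage
    cutoff).
    """
    kmer_list = sorted(set(abundant_kmers))
    graph = DeBruijnGraph(node_k=node_k)
    if not kmer_list:
        return graph
    k = len(kmer_list[0])
    if any(len(x) != k for x in kmer_list):
        raise ParameterError("abundant k-mers must share one length")
    if node_k >= k or node_k % 2 == 0 or k % 2 == 0:
        raise ParameterError("node_k must be odd and smaller than the (odd) input k")

    mult: dict[str, int] = {}
    node_count: dict[str, int] = {}
    for kmer in kmer_list:
        c = counts.get(kmer, 0) if counts else 0
        for i in range(k - node_k + 1):
            node = canonical_kmer(kmer[i : i + node_k])
            graph.nodes.add(node)
            mult[node] = mult.get(node, 0) + 1
            if counts:
                node_count[node] = max(node_count.get(node, 0), c)
    graph.multiplicity = mult
    graph.node_count = node_count

    prefix: dict[str, list[State]] = {}
    suffix: dict[str, list[State]] = {}
    for node in graph.nodes:
        for orient in (1, -1):
            s = _oriented(node, orient)
            prefix.setdefault(s[:-1], []).append((node, orient))
            suffix.setdefault(s[1:], []).append((node, orient))

    edges: set[tuple[State, State]] = set()
    for key, sources in suffix.items():
        targets = prefix.get(key)
        if not targets:
            continue
        for u in sources:
            for v in targets:
                edges.add((u, v))
                edges.add((_rev(v), _rev(u)))
    for u, v in sorted(edges):
        graph.succ.setdefault(u, []).append(v)
    for u in graph.succ:
        graph.succ[u].sort()
    return graph


def _consensus_of(path: list[State]) -> str:
    seq = _oriented(*path[0])
    for state in path[1:]:
        seq += _oriented(*state)[-1]
    return seq


def _canonical_linear(path: list[State]) -> str:
    fwd = _consensus_of(path)
    rev = revcomp(fwd)
    return min(fwd, rev)


def _canonical_cycle(path: list[State]) -> str:
    """Linearize a pure cycle: cut at the lexicographically smallest oriented
    node, in the orientation giving the smaller consensus, and append the
    node_k-1 wraparound bases (implicit in the node concatenation)."""

    def rotate(p: list[State]) -> list[State]:
        i = min(range(len(p)), key=lambda j: _oriented(*p[j]))
        return p[i:] + p[:i]

    fwd = rotate(path)
    rev = rotate([_rev(s) for s in reversed(path)])
    return min(_consensus_of(fwd), _consensus_of(rev))


def assemble_unitigs(graph: DeBruijnGraph, min_length: int = 58) -> list[RepeatConsensus]:
    """Compress maximal non-branching paths into consensus sequences.

    Linear outputs shorter than ``min_length`` are dropped (and counted in
    the log); cyclic outputs are complete tandem units and are always
    kept.  Output order is deterministic: length descending, then
    sequence lexicographic.
    """
    visited: set[str] = set()
    raw: list[tuple[str, bool, list[State]]] = []  # (sequence, is_cyclic, path)

    def is_start(state: State) -> bool:
        if graph.in_degree(state) != 1:
            return True
        (pred_rev,) = graph.successors(_rev(state))
        return graph.out_degree(_rev(pred_rev)) != 1

    for node in sorted(graph.nodes):
        if node in visited:
            continue
        for orient in (1, -1):
            state = (node, orient)
            if node in visited or not is_start(state):
                continue
            path = [state]
            visited.add(node)
            while True:
                cur = path[-1]
                if graph.out_degree(cur) != 1:
                    break
                (nxt,) = graph.successors(cur)
                if graph.in_degree(nxt) != 1 or nxt[0] in visited:
                    break
                path.append(nxt)
                visited.add(nxt[0])
            # a chain whose end reconnects to its start is a tandem cycle
            # cut open by variant side-arms: keep its cyclic identity
            if len(path) > 1 and path[0] in graph.successors(path[-1]):
                raw.append((_canonical_cycle(path), True, path))
            else:
                raw.append((_canonical_linear(path), False, path))
            break

    # leftovers are pure cycles
    for node in sorted(graph.nodes):
        if node in visited:
            continue
        path = [(node, 1)]
        visited.add(node)
        while True:
            cur = path[-1]
            succs = graph.successors(cur)
            if not succs:
                break
            nxt = succs[0]
            if nxt[0] in visited:
                break
            path.append(nxt)
            visited.add(nxt[0])
        raw.append((_canonical_cycle(path), True, path))

    dropped = 0
    out: list[RepeatConsensus] = []
    for seq, cyclic, path in raw:
        if not cyclic and len(seq) < min_length:
            dropped += 1
            continue
        # member count: input k-mer window occurrences carried by this unitig
        out.append(
            RepeatConsensus(
                id="",
                sequence=seq,
                provenance="denovo",
                is_cyclic=cyclic,
                member_kmer_count=sum(graph.multiplicity.get(s[0], 0) for s in path),
                cycle_core=(len(path) if cyclic else None),
            )
        )
    if dropped:
        log.info("assemble_unitigs: dropped %d linear unitigs < %d bp", dropped, min_length)
    branch_states = sum(1 for s, v in graph.succ.items() if len(v) > 1)
    log.info(
        "assemble_unitigs: %d consensus sequences (%d cyclic), %d branching states",
        len(out),
        sum(1 for r in out if r.is_cyclic),
        branch_states,
    )
    out.sort(key=lambda r: (-len(r.sequence), r.sequence))
    for i, rec in enumerate(out):
        rec.id = f"rep{i + 1:05d}"
    return out


def prune_low_coverage(graph: DeBruijnGraph, min_component_frac: float = 0.05) -> DeBruijnGraph:
    """Relative coverage cutoff: within each weakly connected component,
    drop nodes whose k-mer abundance is below ``min_component_frac`` of
    the component maximum.

    A satellite family's consensus k-mers occur at (copy number x k-mer
    coverage) while its recurrent variant k-mers (junction indels,
    inverted-cassette boundaries, shared sequencing errors) sit one to
    two orders of magnitude lower; removing them restores the family's
    clean unit cycle.  Requires the graph to have been built with
    per-k-mer counts; otherwise it is returned unchanged.
    """
    if not graph.node_count or not graph.nodes:
        return graph
    parent: dict[str, str] = {n: n for n in graph.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (u, _), targets in graph.succ.items():
        for v, _ in targets:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[rv] = ru
    comp_max: dict[str, int] = {}
    for n in graph.nodes:
        r = find(n)
        comp_max[r] = max(comp_max.get(r, 0), graph.node_count.get(n, 0))
    keep = {
        n
        for n in graph.nodes
        if graph.node_count.get(n, 0) >= min_component_frac * comp_max[find(n)]
    }
    dropped = len(graph.nodes) - len(keep)
    if dropped:
        log.info("prune_low_coverage: dropped %d of %d nodes", dropped, len(graph.nodes))
    pruned = DeBruijnGraph(node_k=graph.node_k)
    pruned.nodes = keep
    pruned.multiplicity = {n: m for n, m in graph.multiplicity.items() if n in keep}
    pruned.node_count = {n: c for n, c in graph.node_count.items() if n in keep}
    for state, targets in graph.succ.items():
        if state[0] not in keep:
            continue
        kept_targets = [t for t in targets if t[0] in keep]
        if kept_targets:
            pruned.succ[state] = kept_targets
    return pruned


def assemble(
    abundant_kmers,
    node_k: int = 29,
    min_length: int = 58,
    counts: dict[str, int] | None = None,
    min_component_frac: float = 0.05,
) -> list[RepeatConsensus]:
    """Convenience: build the graph, apply the relative coverage cutoff
    (when counts are given) and compress it in one call."""
    graph = build_graph(abundant_kmers, node_k=node_k, counts=counts)
    if counts:
        graph = prune_low_coverage(graph, min_component_frac)
    return assemble_unitigs(graph, min_length=min_length)
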