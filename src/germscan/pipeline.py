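"""End-to-end orchestration: reads in, candidate germline repeat families out.

Stages run in the method's order: k-mer spectrum -> abundance threshold
(3x modal copy number, both tissues, union) -> de Bruijn assembly ->
optional reference-library merge and known-repeat exclusion -> per-tissue
coverage of the repeat library (tandem consensus circularized) -> modal
depth standardization (from scaffolds when provided) -> interval scan ->
enrichment scoring and span estimation -> germline filter (score > 5,
span > 40 kb) -> greedy clustering with cross-merge -> structural
annotation.  A manifest records parameters and stage checksums; rerunning
with an unchanged manifest reloads the expensive early stages from disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import seqs
from .assembly import RepeatConsensus, assemble
from .cluster import ClusterParams, RepeatCluster, cluster_report, cross_merge, greedy_cluster
from .enrich import (
    EnrichmentInterval,
    EnrichmentParams,
    FilterParams,
    MapSeq,
    MappingIndex,
    filter_germline,
    map_coverage,
    modal_depth,
    scan_intervals,
    score_intervals,
    write_bedgraph,
)
from .errors import ParameterError
from .kmers import abundant_kmer_values, count_kmers, modal_copy_number
from .merge import MergeParams, exclude_known, local_align, merge_with_reference
from .synth import SyntheticTruth, write_scenario

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults pin the published analysis values."""

    germline_reads: list[str] = field(default_factory=list)
    somatic_reads: list[str] = field(default_factory=list)
    scaffolds: str | None = None
    reference_library: str | None = None
    known_repeats: str | None = None
    out_dir: str = "germscan_out"

    k: int = 31
    node_k: int = 29
    abundance_multiplier: float = 3.0
    error_peak_min: int = 5
    # the unitig length floor must admit single-unit satellite fragments
    # (a cut cycle of a 13 bp unit is ~41 bp); see the methods note
    min_unitig_length: int = 30
    # relative coverage cutoff within each graph component (Velvet-style)
    min_component_abundance: float = 0.05

    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    filter: FilterParams = field(default_factory=FilterParams)
    merge: MergeParams = field(default_factory=MergeParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)

    somatic_depth_floor: float = 1.0
    fold_estimator: str = "ratio_of_means"
    modal_min_depth: float = 1.0
    map_seed_stride: int = 7  # sample every 7th read window as a placement seed
    period_range: tuple[int, int] = (5, 200)
    periodicity_min_score: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.germline_reads, str):
            self.germline_reads = [self.germline_reads]
        if isinstance(self.somatic_reads, str):
            self.somatic_reads = [self.somatic_reads]
        if self.k % 2 == 0 or self.node_k % 2 == 0 or self.node_k >= self.k:
            raise ParameterError("need odd node_k < odd k")
        if self.abundance_multiplier <= 0:
            raise ParameterError("abundance_multiplier must be > 0")

    @classmethod
    def paper_defaults(cls, **overrides) -> "PipelineConfig":
        """The published parameter profile (these are also the defaults)."""
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        nested = {
            "enrichment": EnrichmentParams,
            "filter": FilterParams,
            "merge": MergeParams,
            "cluster": ClusterParams,
        }
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, val in data.items():
            if key not in known:
                raise ParameterError(f"unknown configuration key: {key}")
            if key in nested and isinstance(val, dict):
                sub_known = {f.name for f in dataclasses.fields(nested[key])}
                bad = set(val) - sub_known
                if bad:
                    raise ParameterError(f"unknown {key} keys: {sorted(bad)}")
                kwargs[key] = nested[key](**val)
            elif key == "period_range":
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_range"] = list(d["period_range"])
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    library: list[RepeatConsensus]
    map_targets: list[MapSeq]
    coverage_germ: dict
    coverage_soma: dict
    modal_germ: float
    modal_soma: float
    intervals: list[EnrichmentInterval]
    candidates: pd.DataFrame
    clusters: list[RepeatCluster]
    cluster_table: pd.DataFrame
    annotations: pd.DataFrame
    funnel: dict[str, int]

    def candidate_records(self) -> list[RepeatConsensus]:
        ids = set(self.candidates["sequence_id"]) if not self.candidates.empty else set()
        return [r for r in self.library if r.id in ids]


def _hash(obj) -> str:
    return hashlib.md5(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _Manifest:
    def __init__(self, path: str):
        self.path = path
        self.data = {"stages": {}}
        if os.path.exists(path):
            try:
                with open(path) as fh:
                    self.data = json.load(fh)
            except (json.JSONDecodeError, OSError):
                pass

    def fresh(self, stage: str, inputs_hash: str, outputs: list[str]) -> bool:
        rec = self.data.get("stages", {}).get(stage)
        return (
            rec is not None
            and rec.get("inputs_hash") == inputs_hash
            and all(os.path.exists(p) for p in rec.get("outputs", []))
            and rec.get("outputs") == outputs
        )

    def record(self, stage: str, inputs_hash: str, outputs: list[str]) -> None:
        self.data.setdefault("stages", {})[stage] = {
            "inputs_hash": inputs_hash,
            "outputs": outputs,
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)


def _library_fasta(path, library: list[RepeatConsensus]) -> None:
    with open(path, "w") as fh:
        for rec in library:
            core = rec.cycle_core if rec.cycle_core else 0
            fh.write(
                f">{rec.id} provenance={rec.provenance} cyclic={int(rec.is_cyclic)} "
                f"core={core} members={rec.member_kmer_count}\n{rec.sequence}\n"
            )


def _library_from_fasta(path) -> list[RepeatConsensus]:
    out = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                header = line[1:]
            elif header is not None:
                fields = dict(
                    kv.split("=") for kv in header.split()[1:] if "=" in kv
                )
                out.append(
                    RepeatConsensus(
                        id=header.split()[0],
                        sequence=line,
                        provenance=fields.get("provenance", "denovo"),
                        is_cyclic=bool(int(fields.get("cyclic", 0))),
                        member_kmer_count=int(fields.get("members", 0)),
                        cycle_core=int(fields.get("core", 0)) or None,
                    )
                )
                header = None
    return out


def _load_reference(path, provenance: str) -> list[RepeatConsensus]:
    return [
        RepeatConsensus(id=name, sequence=seq, provenance=provenance)
        for name, seq in seqs.read_fasta(path)
    ]


def _map_targets(config: PipelineConfig, library: list[RepeatConsensus]) -> list[MapSeq]:
    """Mapping view of the library: tandem consensus circularized to its core."""
    targets = []
    for rec in library:
        core = None
        if rec.is_cyclic and rec.cycle_core:
            core = rec.cycle_core
        elif len(rec.sequence) >= 2 * config.period_range[0]:
            ann = annotate_mod.detect_core_unit(
                rec.sequence, config.period_range, config.periodicity_min_score, rec.id
            )
            if ann.core_unit_length is not None:
                core = ann.core_unit_length
        if core is not None and core >= 5:
            targets.append(MapSeq(rec.id, rec.sequence[:core], circular=True))
        else:
            targets.append(MapSeq(rec.id, rec.sequence, circular=False))
    return targets


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = _Manifest(os.path.join(config.out_dir, "manifest.json"))
    funnel: dict[str, int] = {}

    # -- stage 1: abundant k-mers (both tissues, union) --------------------
    abundant_path = os.path.join(config.out_dir, "abundant_kmers.txt")
    h1 = _hash(
        dict(
            stage="abundant",
            k=config.k,
            mult=config.abundance_multiplier,
            peak=config.error_peak_min,
            germ=config.germline_reads,
            soma=config.somatic_reads,
        )
    )
    meta_path = os.path.join(config.out_dir, "spectrum_meta.json")
    if manifest.fresh("abundant", h1, [abundant_path, meta_path]):
        log.info("abundant: reusing %s", abundant_path)
        union_counts: dict[str, int] = {}
        with open(abundant_path) as fh:
            for line in fh:
                if line.strip():
                    km, c = line.split()
                    union_counts[km] = int(c)
        with open(meta_path) as fh:
            spectrum_meta = json.load(fh)
    else:
        spectrum_meta = {}
        sample_counts = []
        for name, paths in (("germline", config.germline_reads), ("somatic", config.somatic_reads)):
            spec = count_kmers(paths, config.k)
            mode = modal_copy_number(spec, config.error_peak_min)
            vals = abundant_kmer_values(spec, config.abundance_multiplier)
            sel = np.searchsorted(spec.kmers, vals)
            cnts = spec.counts[sel]
            spectrum_meta[name] = {
                "modal_copy_number": mode,
                "abundance_threshold": spec.abundance_threshold,
                "distinct_kmers": len(spec),
                "abundant_kmers": int(vals.size),
            }
            sample_counts.append((vals, cnts))
            log.info(
                "spectrum[%s]: mode=%d threshold=%.0f abundant=%d",
                name, mode, spec.abundance_threshold, vals.size,
            )
            del spec
        # union of the two tissues' abundant sets; keep the larger count
        union_counts = {}
        for vals, cnts in sample_counts:
            for v, c in zip(vals, cnts):
                km = seqs.value_to_kmer(int(v), config.k)
                union_counts[km] = max(union_counts.get(km, 0), int(c))
        with open(abundant_path, "w") as fh:
            for km in sorted(union_counts):
                fh.write(f"{km}\t{union_counts[km]}\n")
        with open(meta_path, "w") as fh:
            json.dump(spectrum_meta, fh, indent=1)
        manifest.record("abundant", h1, [abundant_path, meta_path])
    union = sorted(union_counts)
    funnel["abundant_kmers"] = len(union)

    # -- stage 2: assembly + library merge ---------------------------------
    library_path = os.path.join(config.out_dir, "library.fa")
    h2 = _hash(
        dict(
            stage="library",
            h1=h1,
            node_k=config.node_k,
            min_len=config.min_unitig_length,
            ref=config.reference_library,
            known=config.known_repeats,
            merge=dataclasses.asdict(config.merge),
        )
    )
    if manifest.fresh("library", h2, [library_path]):
        log.info("library: reusing %s", library_path)
        library = _library_from_fasta(library_path)
    else:
        library = assemble(
            union,
            node_k=config.node_k,
            min_length=config.min_unitig_length,
            counts=union_counts,
            min_component_frac=config.min_component_abundance,
        )
        if config.reference_library:
            library = merge_with_reference(
                library, _load_reference(config.reference_library, "reference"), config.merge
            )
        if config.known_repeats:
            library = exclude_known(
                library,
                _load_reference(config.known_repeats, "known"),
                config.merge.known_identity,
                params=config.merge,
            )
        _library_fasta(library_path, library)
        manifest.record("library", h2, [library_path])
    funnel["library_sequences"] = len(library)

    # -- stage 3: coverage + modal depths ----------------------------------
    targets = _map_targets(config, library)
    cov_paths = {
        "germ": os.path.join(config.out_dir, "coverage_germline.bedgraph"),
        "soma": os.path.join(config.out_dir, "coverage_somatic.bedgraph"),
    }
    depth_meta_path = os.path.join(config.out_dir, "coverage_meta.json")
    h3 = _hash(dict(stage="coverage", h2=h2, k=config.k, scaffolds=config.scaffolds,
                    modal_min_depth=config.modal_min_depth))
    if manifest.fresh("coverage", h3, [cov_paths["germ"], cov_paths["soma"], depth_meta_path]):
        log.info("coverage: reusing bedGraphs")
        from .enrich import read_bedgraph

        lengths = {t.seq_id: len(t.sequence) for t in targets}
        cov_germ = read_bedgraph(cov_paths["germ"], lengths)
        cov_soma = read_bedgraph(cov_paths["soma"], lengths)
        with open(depth_meta_path) as fh:
            depth_meta = json.load(fh)
        modal_germ, modal_soma = depth_meta["modal_germ"], depth_meta["modal_soma"]
    else:
        indices = [MappingIndex(targets, config.k)]
        if config.scaffolds:
            indices.append(
                MappingIndex(
                    [MapSeq(sid, s) for sid, s in seqs.read_fasta(config.scaffolds)],
                    config.k,
                )
            )
        res_g = map_coverage(config.germline_reads, indices, config.map_seed_stride)
        res_s = map_coverage(config.somatic_reads, indices, config.map_seed_stride)
        cov_germ, unplaced_g = res_g[0]
        cov_soma, unplaced_s = res_s[0]
        log.info("coverage: unplaced germ=%d soma=%d", unplaced_g, unplaced_s)
        if config.scaffolds:
            modal_germ = modal_depth(res_g[1][0], config.modal_min_depth)
            modal_soma = modal_depth(res_s[1][0], config.modal_min_depth)
        else:
            modal_germ = modal_depth(cov_germ, config.modal_min_depth)
            modal_soma = modal_depth(cov_soma, config.modal_min_depth)
        del res_g, res_s, indices
        write_bedgraph(cov_germ, cov_paths["germ"])
        write_bedgraph(cov_soma, cov_paths["soma"])
        depth_meta = {
            "modal_germ": modal_germ,
            "modal_soma": modal_soma,
            "unplaced_germ": unplaced_g,
            "unplaced_soma": unplaced_s,
        }
        with open(depth_meta_path, "w") as fh:
            json.dump(depth_meta, fh, indent=1)
        manifest.record("coverage", h3, [cov_paths["germ"], cov_paths["soma"], depth_meta_path])
    log.info("modal depths: germline=%s somatic=%s", modal_germ, modal_soma)

    # -- stage 4: intervals, scores, spans, filter -------------------------
    intervals = scan_intervals(cov_germ, cov_soma, config.enrichment)
    lengths = {t.seq_id: len(t.sequence) for t in targets}
    score_intervals(
        intervals,
        lengths,
        modal_germ,
        modal_soma,
        config.somatic_depth_floor,
        config.fold_estimator,
    )
    funnel["intervals"] = len(intervals)
    kept = filter_germline(intervals, config.filter)
    funnel["filtered_intervals"] = len(kept)

    rows = [
        dict(
            sequence_id=iv.sequence_id,
            start=iv.start,
            end=iv.end,
            n_eligible=iv.n_eligible,
            mean_depth_germline=iv.mean_depth_1,
            mean_depth_somatic=iv.mean_depth_2,
            enrichment_score=iv.enrichment_score,
            estimated_span=iv.estimated_span,
        )
        for iv in kept
    ]
    candidates = pd.DataFrame(
        rows,
        columns=[
            "sequence_id", "start", "end", "n_eligible", "mean_depth_germline",
            "mean_depth_somatic", "enrichment_score", "estimated_span",
        ],
    )
    candidates.to_csv(os.path.join(config.out_dir, "candidates.tsv"), sep="\t", index=False)

    # -- stage 5: clustering ----------------------------------------------
    by_id = {r.id: r for r in library}
    cand_ids = list(dict.fromkeys(candidates["sequence_id"])) if not candidates.empty else []
    cand_records = [by_id[i] for i in cand_ids]
    spans = (
        candidates.groupby("sequence_id")["estimated_span"].sum().to_dict()
        if not candidates.empty
        else {}
    )
    clusters = greedy_cluster(cand_records, spans, config.cluster)
    funnel["clusters_greedy"] = len(clusters)
    clusters = cross_merge(clusters, cand_records, config.cluster)
    funnel["clusters_merged"] = len(clusters)
    table = cluster_report(clusters, cand_records)
    table.to_csv(os.path.join(config.out_dir, "clusters.tsv"), sep="\t", index=False)

    # -- stage 6: structural annotation ------------------------------------
    scaffold_records = seqs.read_fasta(config.scaffolds) if config.scaffolds else []
    ann_rows = []
    for rec in cand_records:
        try:
            ann = annotate_mod.detect_core_unit(
                rec.sequence, config.period_range, config.periodicity_min_score, rec.id
            )
        except ParameterError:
            ann = annotate_mod.TandemAnnotation(rec.id, None, None, 0.0)
        cassettes = annotate_mod.find_inverted_cassettes(rec.sequence, params=config.merge) \
            if len(rec.sequence) >= 200 else []
        assignment = (
            annotate_mod.assign_scaffold(rec, scaffold_records, params=MergeParams(
                seed_word_size=config.merge.seed_word_size, max_extensions=3000))
            if scaffold_records
            else annotate_mod.ScaffoldAssignment(rec.id, None, 0, 0.0)
        )
        ann_rows.append(
            dict(
                sequence_id=rec.id,
                is_cyclic=rec.is_cyclic,
                core_unit_length=ann.core_unit_length,
                core_consensus=ann.core_consensus,
                periodicity_score=ann.periodicity_score,
                n_inverted_cassettes=len(cassettes),
                scaffold_id=assignment.scaffold_id,
                scaffold_hits=assignment.hit_count,
            )
        )
    annotations = pd.DataFrame(
        ann_rows,
        columns=[
            "sequence_id", "is_cyclic", "core_unit_length", "core_consensus",
            "periodicity_score", "n_inverted_cassettes", "scaffold_id", "scaffold_hits",
        ],
    )
    annotations.to_csv(os.path.join(config.out_dir, "annotations.tsv"), sep="\t", index=False)

    with open(os.path.join(config.out_dir, "funnel.json"), "w") as fh:
        json.dump(funnel, fh, indent=1)
    log.info("funnel: %s", funnel)

    return PipelineResult(
        config=config,
        library=library,
        map_targets=targets,
        coverage_germ=cov_germ,
        coverage_soma=cov_soma,
        modal_germ=modal_germ,
        modal_soma=modal_soma,
        intervals=intervals,
        candidates=candidates,
        clusters=clusters,
        cluster_table=table,
        annotations=annotations,
        funnel=funnel,
    )


# ---------------------------------------------------------------------------
# recovery evaluation against a synthetic truth table


@dataclass
class RecoveryReport:
    per_family: pd.DataFrame
    precision: float
    recall: float
    score_mae: float          # mean |measured - expected| over detected restricted families
    max_span_rel_error: float  # max relative span error over detected restricted families

    def __post_init__(self) -> None:
        if not (0.0 <= self.precision <= 1.0 and 0.0 <= self.recall <= 1.0):
            raise ParameterError("precision and recall must be within [0, 1]")


def _family_identity(unit: str, record: RepeatConsensus) -> float:
    """Best identity between a planted core unit and a consensus, rotation-aware."""
    from .merge import alignment_sequence

    subject = alignment_sequence(record)
    if len(subject) < len(unit) * 2:
        subject = record.sequence * (2 * len(unit) // max(1, len(record.sequence)) + 2)
    w = min(11, len(unit) - 2)
    hits = local_align(unit * 2, subject, MergeParams(seed_word_size=max(5, w)))
    best = 0.0
    for h in hits:
        if (h.query_end - h.query_start) >= 0.9 * len(unit):
            best = max(best, h.identity)
    return best


def evaluate_recovery(
    result: PipelineResult,
    truth: SyntheticTruth,
    coverage: float,
    depth_floor: float = 1.0,
    min_identity: float = 0.9,
) -> RecoveryReport:
    """Match pipeline candidates to planted families and grade the run.

    A candidate matches a family when a rotation-aware alignment to the
    planted unit reaches ``min_identity`` over >= 90% of the unit.
    Precision counts candidates matching restricted families; recall
    counts restricted families with at least one matched candidate.
    """
    by_id = {r.id: r for r in result.library}
    cand_ids = (
        list(dict.fromkeys(result.candidates["sequence_id"]))
        if not result.candidates.empty
        else []
    )
    # match every library sequence that was scored (pre-filter) so that
    # correctly-rejected shared families still report a measured score
    scored_ids = list(dict.fromkeys(iv.sequence_id for iv in result.intervals))
    assignment_all: dict[str, str] = {}
    for sid in scored_ids:
        best_fam, best_ident = None, 0.0
        for fam in truth.families:
            ident = _family_identity(fam.unit_seq, by_id[sid])
            if ident > best_ident:
                best_fam, best_ident = fam.family_id, ident
        if best_fam is not None and best_ident >= min_identity:
            assignment_all[sid] = best_fam
    assignment = {c: f for c, f in assignment_all.items() if c in set(cand_ids)}

    cand_spans = (
        result.candidates.groupby("sequence_id")["estimated_span"].sum().to_dict()
        if not result.candidates.empty
        else {}
    )
    all_scores: dict[str, float] = {}
    for iv in result.intervals:
        if iv.enrichment_score is not None:
            prev = all_scores.get(iv.sequence_id)
            if prev is None or iv.enrichment_score > prev:
                all_scores[iv.sequence_id] = iv.enrichment_score
    cluster_of = {
        m: c.cluster_id for c in result.clusters for m in c.member_ids
    }
    fam_of_cluster: dict[str, set[str]] = {}
    for cid, fam in assignment.items():
        cl = cluster_of.get(cid)
        if cl:
            fam_of_cluster.setdefault(cl, set()).add(fam)

    rows = []
    restricted = [f for f in truth.families if f.restricted]
    for fam in truth.families:
        matched = [c for c, f in assignment.items() if f == fam.family_id]
        matched_any = [c for c, f in assignment_all.items() if f == fam.family_id]
        detected = bool(matched)
        planted = truth.planted_span(fam.family_id)
        span = sum(cand_spans.get(c, 0.0) for c in matched)
        score = max(
            (all_scores[c] for c in matched_any if c in all_scores),
            default=float("nan"),
        )
        expected = truth.expected_score(fam.family_id, coverage, depth_floor)
        fam_clusters = {cluster_of.get(c) for c in matched} - {None}
        if not fam_clusters:
            corr = "absent"
        elif len(fam_clusters) > 1:
            corr = "split"
        elif any(len(fam_of_cluster.get(cl, set())) > 1 for cl in fam_clusters):
            corr = "merged"
        else:
            corr = "1:1"
        best_ident = max(
            (_family_identity(fam.unit_seq, by_id[c]) for c in matched_any), default=0.0
        )
        rows.append(
            dict(
                family_id=fam.family_id,
                restricted=fam.restricted,
                detected=detected,
                n_candidates=len(matched),
                best_identity=best_ident,
                measured_score=score,
                expected_score=expected,
                score_error=(score - expected) if detected else float("nan"),
                planted_span=planted,
                estimated_span=span,
                span_rel_error=(abs(span - planted) / planted) if detected and planted else float("nan"),
                cluster_correspondence=corr,
            )
        )
    per_family = pd.DataFrame(rows)

    n_cand = len(cand_ids)
    matched_restricted = {f for f in assignment.values() if f in {r.family_id for r in restricted}}
    precision = (
        sum(1 for c in cand_ids if assignment.get(c) in matched_restricted) / n_cand
        if n_cand
        else 1.0
    )
    recall = len(matched_restricted) / len(restricted) if restricted else 1.0
    det = per_family[(per_family.restricted) & (per_family.detected)]
    score_mae = float(det["score_error"].abs().mean()) if len(det) else float("nan")
    max_span_err = float(det["span_rel_error"].max()) if len(det) else float("nan")
    return RecoveryReport(per_family, precision, recall, score_mae, max_span_err)


# ---------------------------------------------------------------------------
# packaged standard scenario


def run_standard_scenario(workdir, seed: int = 0, config_overrides: dict | None = None):
    """Simulate the standard scenario under ``workdir`` and run the pipeline.

    Returns (PipelineResult, SyntheticTruth, scenario paths).
    """
    from .synth import standard_scenario

    scen_dir = os.path.join(workdir, "scenario")
    paths = write_scenario(scen_dir, seed)
    _, _, truth, _, _ = standard_scenario(seed)
    cfg = dict(
        germline_reads=[paths["germline_reads"]],
        somatic_reads=[paths["somatic_reads"]],
        scaffolds=paths["germline_fasta"],
        out_dir=os.path.join(workdir, "out"),
        seed=seed,
    )
    cfg.update(config_overrides or {})
    config = PipelineConfig.paper_defaults(**cfg)
    result = run_pipeline(config)
    return result, truth, paths
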