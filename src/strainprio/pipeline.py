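"""End-to-end orchestration: simulate → cluster → screen → qc → prioritize
→ evaluate → report.

Each stage reads only the artifacts of its upstream stages (plain TSV/JSON
on disk), writes its own, and records a provenance JSON (config hash,
input hashes, versions, counts). Rerunning a stage with identical inputs
and config yields identical artifacts.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .clustering import (
    UNCLUSTERED,
    Cluster,
    annotate_clusters,
    assign_from_hits,
    greedy_cluster,
    write_clusters_tsv,
)
from .mapping_eval import (
    clean_reads,
    coverage_profiles,
    enrichment_test,
    filter_sample_outliers,
    high_representation,
    improvement_summary,
    per_site_report,
    summarize_mapping,
    write_improvement_tsv,
)
from .novelty import call_novelty, status_counts, write_novelty_tsv
from .prioritization import RankingConfig, assign_tiers, select_top_n, write_priority_tsv
from .qc import (
    choose_representative_replicates,
    collapse_body_site,
    detect_replicate_conflicts,
    write_contamination_tsv,
)
from .sequence_core import (
    DEFAULT_SCORING,
    AlignmentHit,
    AlignmentScoring,
    align_pair,
    read_fasta_with_metadata,
    read_reference_fasta,
    select_best,
    write_hits_tsv,
)
from .synthetic import SimulationConfig, simulate_all

logger = logging.getLogger("strainprio")

STAGES = ["simulate", "cluster", "screen", "qc", "prioritize", "evaluate", "report"]


@dataclass
class PipelineConfig:
    outdir: str = "strainprio_out"
    seed: int = 1
    novelty_id: float = 97.0  # percent
    novelty_cov: float = 90.0  # percent
    cluster_id: float = 99.0  # percent
    cluster_cov: float = 95.0  # percent
    breadth_cut: float = 0.5
    depth_cut: float = 1.0
    n_select: int | None = None  # None = all tiered samples
    unavailable: list[str] = field(default_factory=list)
    ranking: RankingConfig = field(default_factory=RankingConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def __post_init__(self) -> None:
        for name, value, lo, hi in [
            ("novelty_id", self.novelty_id, 0, 100),
            ("novelty_cov", self.novelty_cov, 0, 100),
            ("cluster_id", self.cluster_id, 0, 100),
            ("cluster_cov", self.cluster_cov, 0, 100),
            ("breadth_cut", self.breadth_cut, 0, 1),
            ("depth_cut", self.depth_cut, 0, float("inf")),
        ]:
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        self.sim.seed = self.seed

    # --- paths -------------------------------------------------------------
    @property
    def out(self) -> Path:
        return Path(self.outdir)

    @property
    def sim_dir(self) -> Path:
        return self.out / "sim"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "ranking" in raw:
            raw["ranking"] = RankingConfig(**raw["ranking"])
        if "sim" in raw:
            raw["sim"] = SimulationConfig(**raw["sim"])
        if "scoring" in raw:
            raw["scoring"] = AlignmentScoring(**raw["scoring"])
        return cls(**raw)


class MissingArtifactError(FileNotFoundError):
    pass


def _require(config: PipelineConfig, paths: Sequence[Path], stage_needed: str) -> None:
    for p in paths:
        if not p.exists():
            raise MissingArtifactError(
                f"missing artifact {p}; run stage '{stage_needed}' first"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(
    config: PipelineConfig, stage: str, inputs: Sequence[Path], counts: Mapping[str, int]
) -> None:
    prov_dir = config.out / "provenance"
    prov_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "stage": stage,
        "version": __version__,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {str(p): _sha256(p) for p in inputs if p.is_file()},
        "counts": dict(counts),
    }
    (prov_dir / f"{stage}.json").write_text(json.dumps(record, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(config: PipelineConfig) -> dict:
    truth = simulate_all(config.sim, config.sim_dir)
    n = len(truth["samples"])
    _provenance(config, "simulate", [], {"query_samples": n})
    logger.info("simulate: %d query samples, %d read samples", n, len(truth["reads"]["samples"]))
    return {"n_samples": n}


def _load_references(config: PipelineConfig):
    return read_reference_fasta(config.sim_dir / "references.fasta", config.sim_dir / "references.tsv")


def _load_clusters(config: PipelineConfig) -> tuple[list[Cluster], dict[str, str]]:
    refs = _load_references(config)
    seqs = {r.ref_id: r.sequence for r in refs}
    members: dict[str, tuple[str, list[str]]] = {}
    with open(config.out / "clusters.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cid = row["cluster_id"]
            members.setdefault(cid, (row["representative_id"], []))[1].append(row["member_id"])
    clusters = [
        Cluster(
            cluster_id=cid,
            representative_id=rep,
            member_ids=mids,
            id_threshold=config.cluster_id / 100.0,
            cov_threshold=config.cluster_cov / 100.0,
        )
        for cid, (rep, mids) in sorted(members.items())
    ]
    annotate_clusters(clusters, refs)
    return clusters, seqs


def _stage_cluster(config: PipelineConfig) -> dict:
    inputs = [config.sim_dir / "references.fasta", config.sim_dir / "references.tsv"]
    _require(config, inputs, "simulate")
    refs = _load_references(config)
    seqs = {r.ref_id: r.sequence for r in refs}
    clusters = greedy_cluster(
        sorted(seqs.items()),
        id_threshold=config.cluster_id / 100.0,
        cov_threshold=config.cluster_cov / 100.0,
        scoring=config.scoring,
    )
    annotate_clusters(clusters, refs)
    write_clusters_tsv(clusters, seqs, config.out / "clusters.tsv", config.scoring)
    _provenance(config, "cluster", inputs, {"references": len(refs), "clusters": len(clusters)})
    logger.info("cluster: %d references -> %d clusters", len(refs), len(clusters))
    return {"n_clusters": len(clusters)}


def _stage_screen(config: PipelineConfig) -> dict:
    """Per-replicate best hits against the reference set plus cluster assignment."""
    inputs = [
        config.sim_dir / "queries.fasta",
        config.sim_dir / "queries.tsv",
        config.out / "clusters.tsv",
    ]
    _require(config, inputs[:2], "simulate")
    _require(config, inputs[2:], "cluster")
    records = read_fasta_with_metadata(config.sim_dir / "queries.fasta", config.sim_dir / "queries.tsv")
    refs = _load_references(config)
    clusters, _ = _load_clusters(config)
    best_hits: list[AlignmentHit] = []
    assignments: dict[str, str] = {}
    for rec in records:
        hits = [
            align_pair(rec.sequence, ref.sequence, rec.record_id, ref.ref_id, config.scoring)
            for ref in sorted(refs, key=lambda r: r.ref_id)
        ]
        best = select_best(hits, config.scoring.min_score)
        if best is not None:
            best_hits.append(best)
        assignments[rec.record_id] = assign_from_hits(
            hits, clusters, config.cluster_id / 100.0, config.cluster_cov / 100.0
        )
    write_hits_tsv(best_hits, config.out / "hits.tsv")
    with open(config.out / "assignments.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["record_id", "cluster_id"])
        for rid in sorted(assignments):
            writer.writerow([rid, assignments[rid]])
    n_unclustered = sum(1 for v in assignments.values() if v == UNCLUSTERED)
    _provenance(
        config,
        "screen",
        inputs,
        {"replicates": len(records), "hits": len(best_hits), "unclustered": n_unclustered},
    )
    logger.info("screen: %d replicates, %d unclustered", len(records), n_unclustered)
    return {"n_replicates": len(records)}


def _read_assignments(config: PipelineConfig) -> dict[str, str]:
    with open(config.out / "assignments.tsv", newline="") as fh:
        return {row["record_id"]: row["cluster_id"] for row in csv.DictReader(fh, delimiter="\t")}


def _read_hits(config: PipelineConfig) -> dict[str, AlignmentHit]:
    hits = {}
    with open(config.out / "hits.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hits[row["qseqid"]] = AlignmentHit(
                query_id=row["qseqid"],
                subject_id=row["sseqid"],
                pct_identity=float(row["pident"]),
                query_coverage=float(row["qcovs"]),
                aln_length=int(row["length"]),
                q_start=int(row["qstart"]),
                q_end=int(row["qend"]),
                s_start=int(row["sstart"]),
                s_end=int(row["send"]),
                score=float(row["score"]),
            )
    return hits


def _stage_qc(config: PipelineConfig) -> dict:
    inputs = [
        config.sim_dir / "queries.fasta",
        config.sim_dir / "queries.tsv",
        config.out / "assignments.tsv",
    ]
    _require(config, inputs[2:], "screen")
    records = read_fasta_with_metadata(config.sim_dir / "queries.fasta", config.sim_dir / "queries.tsv")
    assignments = _read_assignments(config)
    reports = detect_replicate_conflicts(
        records,
        assignments,
        config.cluster_id / 100.0,
        config.cluster_cov / 100.0,
        config.scoring,
    )
    write_contamination_tsv(reports, config.out / "contamination.tsv")
    representatives = choose_representative_replicates(records, reports)
    with open(config.out / "representatives.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "replicate_id"])
        for rec in representatives:
            writer.writerow([rec.sample_id, rec.replicate_id])
    n_cont = sum(r.contaminated for r in reports)
    _provenance(
        config,
        "qc",
        inputs,
        {"samples": len(reports), "contaminated": n_cont, "clean": len(reports) - n_cont},
    )
    logger.info("qc: %d samples, %d contaminated", len(reports), n_cont)
    return {"n_contaminated": n_cont}


def _stage_prioritize(config: PipelineConfig) -> dict:
    inputs = [
        config.out / "hits.tsv",
        config.out / "assignments.tsv",
        config.out / "representatives.tsv",
        config.out / "clusters.tsv",
    ]
    _require(config, inputs[:2], "screen")
    _require(config, inputs[2:3], "qc")
    _require(config, inputs[3:], "cluster")
    records = read_fasta_with_metadata(config.sim_dir / "queries.fasta", config.sim_dir / "queries.tsv")
    by_record = {r.record_id: r for r in records}
    with open(config.out / "representatives.tsv", newline="") as fh:
        rep_records = [
            by_record[f"{row['sample_id']}.{row['replicate_id']}"]
            for row in csv.DictReader(fh, delimiter="\t")
        ]
    hits = _read_hits(config)
    assignments = _read_assignments(config)
    clusters, _ = _load_clusters(config)
    cluster_map = {c.cluster_id: c for c in clusters}

    sample_hits = {r.sample_id: hits.get(r.record_id) for r in rep_records}
    sample_assign = {r.sample_id: assignments[r.record_id] for r in rep_records}
    body_sites = {}
    lengths = {}
    for r in rep_records:
        broad = r.body_site_broad
        if not broad or broad == "Unknown":
            broad = collapse_body_site(r.body_site_detailed)
        body_sites[r.sample_id] = broad
        lengths[r.sample_id] = r.length

    calls = call_novelty(
        rep_records, sample_hits, sample_assign, cluster_map, config.novelty_id, config.novelty_cov
    )
    write_novelty_tsv(calls, config.out / "novelty.tsv")
    tiers = assign_tiers(calls, lengths, body_sites, config.ranking)
    n_tiered = sum(1 for t in tiers if t.tier is not None)
    n = config.n_select if config.n_select is not None else n_tiered
    selection = select_top_n(tiers, n, frozenset(config.unavailable))
    write_priority_tsv(selection, config.out / "priorities.tsv")
    with open(config.out / "tiers.tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "tier", "within_tier_rank", "cluster_id", "novelty_status", "body_site_broad"])
        for a in sorted(tiers, key=lambda a: (a.tier or 99, a.within_tier_rank, a.sample_id)):
            writer.writerow(
                [a.sample_id, a.tier if a.tier is not None else "NA", a.within_tier_rank, a.cluster_id, a.novelty_status, a.body_site_broad]
            )
    counts = status_counts(calls)
    counts["selected"] = len(selection)
    _provenance(config, "prioritize", inputs, counts)
    logger.info("prioritize: %s, %d selected", dict(counts), len(selection))
    return {"status_counts": counts, "n_selected": len(selection)}


def _stage_evaluate(config: PipelineConfig) -> dict:
    reads_dir = config.sim_dir / "reads"
    inputs = [reads_dir / "read_samples.tsv", config.sim_dir / "genome_metadata.tsv"]
    _require(config, inputs, "simulate")
    with open(inputs[1], newline="") as fh:
        genome_meta = {row["genome_id"]: row for row in csv.DictReader(fh, delimiter="\t")}
    genome_phylum = {g: m["phylum"] for g, m in genome_meta.items()}
    with open(inputs[0], newline="") as fh:
        read_samples = list(csv.DictReader(fh, delimiter="\t"))

    cleaned_counts = {}
    for row in read_samples:
        _, counts = clean_reads(reads_dir / row["fastq"])
        cleaned_counts[row["sample_id"]] = counts["kept"]
    body_sites = {row["sample_id"]: row["body_site"] for row in read_samples}
    retained = filter_sample_outliers(cleaned_counts, body_sites)

    summaries = []
    high_flags: dict[str, bool] = {}
    for row in read_samples:
        sid = row["sample_id"]
        if sid not in retained:
            continue
        summaries.append(
            summarize_mapping(
                sid,
                row["body_site"],
                cleaned_counts[sid],
                reads_dir / row["baseline_sam"],
                reads_dir / row["augmented_sam"],
                genome_phylum,
            )
        )
        for profile in coverage_profiles(reads_dir / row["augmented_sam"]):
            if high_representation(profile, config.breadth_cut, config.depth_cut):
                high_flags[profile.genome_id] = True
            else:
                high_flags.setdefault(profile.genome_id, False)

    for group_by in ("body_site", "phylum", "sample"):
        write_improvement_tsv(
            improvement_summary(summaries, group_by), config.out / f"improvement_by_{group_by}.tsv"
        )
    per_site_report(summaries).to_csv(
        config.out / "per_site_report.tsv", sep="\t", index=False, float_format="%.1f"
    )

    novel_genomes = sorted(g for g, m in genome_meta.items() if m["source"] == "novel")
    public_genomes = sorted(g for g, m in genome_meta.items() if m["source"] == "public")
    high_novel = sum(high_flags.get(g, False) for g in novel_genomes)
    high_public = sum(high_flags.get(g, False) for g in public_genomes)
    p_enrich = enrichment_test(high_novel, len(novel_genomes), high_public, len(public_genomes))

    total_base = sum(s.n_mapped_baseline for s in summaries)
    total_aug = sum(s.n_mapped_augmented for s in summaries)
    result = {
        "n_read_samples": len(read_samples),
        "n_retained_samples": len(summaries),
        "total_mapped_baseline": total_base,
        "total_mapped_augmented": total_aug,
        "relative_increase_pct": 100.0 * (total_aug - total_base) / total_base if total_base else None,
        "high_representation": {
            "novel": [high_novel, len(novel_genomes)],
            "public": [high_public, len(public_genomes)],
        },
        "enrichment_p": p_enrich,
    }
    (config.out / "evaluation.json").write_text(json.dumps(result, indent=1, sort_keys=True))
    _provenance(
        config,
        "evaluate",
        inputs,
        {"read_samples": len(read_samples), "retained": len(summaries)},
    )
    logger.info(
        "evaluate: +%.2f%% mapped reads, enrichment p=%.3g",
        result["relative_increase_pct"] or 0.0,
        p_enrich,
    )
    return result


def _stage_report(config: PipelineConfig) -> dict:
    inputs = [
        config.out / "contamination.tsv",
        config.out / "novelty.tsv",
        config.out / "priorities.tsv",
        config.out / "evaluation.json",
    ]
    _require(config, inputs[:1], "qc")
    _require(config, inputs[1:3], "prioritize")
    _require(config, inputs[3:], "evaluate")
    with open(inputs[0], newline="") as fh:
        cont_rows = list(csv.DictReader(fh, delimiter="\t"))
    with open(inputs[1], newline="") as fh:
        novelty_rows = list(csv.DictReader(fh, delimiter="\t"))
    with open(inputs[2], newline="") as fh:
        priority_rows = list(csv.DictReader(fh, delimiter="\t"))
    evaluation = json.loads(inputs[3].read_text())

    n_input = len(cont_rows)
    n_cont = sum(int(r["contaminated"]) for r in cont_rows)
    funnel = {
        "input_samples": n_input,
        "classified_samples": n_input,
        "contaminated_samples": n_cont,
        "post_contamination_samples": n_input - n_cont,
        "prioritized_samples": len(priority_rows),
    }
    by_status = Counter(r["status"] for r in novelty_rows)
    by_site = Counter(r["body_site_broad"] for r in priority_rows)
    by_tier = Counter(int(r["tier"]) for r in priority_rows)
    report = {
        "funnel": funnel,
        "novelty_status_counts": dict(sorted(by_status.items())),
        "prioritized_by_body_site": dict(sorted(by_site.items())),
        "prioritized_by_tier": {str(k): v for k, v in sorted(by_tier.items())},
        "mapping_evaluation": evaluation,
    }
    (config.out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    _provenance(config, "report", inputs, funnel)
    logger.info("report: funnel %s", funnel)
    return report


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cluster": _stage_cluster,
    "screen": _stage_screen,
    "qc": _stage_qc,
    "prioritize": _stage_prioritize,
    "evaluate": _stage_evaluate,
    "report": _stage_report,
}


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one named stage; upstream artifacts must already exist."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    config.out.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[stage](config)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the final report."""
    result = {}
    for stage in STAGES:
        result = run_stage(stage, config)
    return result
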