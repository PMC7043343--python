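"""Greedy identity/coverage clustering and query-to-representative assignment.

CD-HIT-style greedy clustering: sequences are visited longest-first, each
joining the best-matching existing representative that passes BOTH the
identity and the coverage threshold, otherwise founding a new cluster.
The representative of a cluster is therefore its longest member by
construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .sequence_core import (
    DEFAULT_SCORING,
    AlignmentHit,
    AlignmentScoring,
    ReferenceEntry,
    align_pair,
)

UNCLUSTERED = "UNCLUSTERED"


@dataclass
class Cluster:
    cluster_id: str
    representative_id: str
    member_ids: list[str]
    id_threshold: float
    cov_threshold: float
    contains_sequenced_genome: bool = False
    member_body_sites: set[str] = field(default_factory=set)
    sequenced_genome_body_sites: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError(f"{self.cluster_id}: representative not a member")


def _canonical_order(records: Sequence[tuple[str, str]]) -> list[tuple[str, str]]:
    # longest first, ties broken on lexicographic id → deterministic in input order
    return sorted(records, key=lambda r: (-len(r[1]), r[0]))


def _passes(hit: AlignmentHit | None, id_threshold: float, cov_threshold: float) -> bool:
    return (
        hit is not None
        and hit.pct_identity >= 100.0 * id_threshold
        and hit.query_coverage >= 100.0 * cov_threshold
    )


def greedy_cluster(
    records: Sequence[tuple[str, str]],
    id_threshold: float = 0.99,
    cov_threshold: float = 0.95,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[Cluster]:
    """Cluster ``(seq_id, sequence)`` records greedily, longest-first.

    A record joins the representative with the highest identity among those
    passing both thresholds (identity AND coverage, both inclusive); the
    member sequence is the alignment query, so coverage is of the member.
    Output clusters partition the input.
    """
    if not records:
        raise ValueError("greedy_cluster requires at least one record")
    if not (0 < id_threshold <= 1 and 0 < cov_threshold <= 1):
        raise ValueError("thresholds must be in (0, 1]")
    reps: list[tuple[str, str]] = []  # (rep_id, rep_seq), in founding order
    members: dict[str, list[str]] = {}
    for seq_id, seq in _canonical_order(records):
        best_rep: str | None = None
        best_key: tuple[float, float] | None = None
        for rep_id, rep_seq in reps:
            hit = align_pair(seq, rep_seq, seq_id, rep_id, scoring)
            if _passes(hit, id_threshold, cov_threshold):
                key = (hit.pct_identity, hit.query_coverage)
                if best_key is None or key > best_key:
                    best_key, best_rep = key, rep_id
        if best_rep is None:
            reps.append((seq_id, seq))
            members[seq_id] = [seq_id]
        else:
            members[best_rep].append(seq_id)
    return [
        Cluster(
            cluster_id=f"C{i + 1:04d}",
            representative_id=rep_id,
            member_ids=members[rep_id],
            id_threshold=id_threshold,
            cov_threshold=cov_threshold,
        )
        for i, (rep_id, _) in enumerate(reps)
    ]


def annotate_clusters(
    clusters: Iterable[Cluster], refs: Iterable[ReferenceEntry]
) -> None:
    """Fill sequenced-genome flags and body-site sets from reference metadata."""
    by_id = {r.ref_id: r for r in refs}
    for cluster in clusters:
        for member in cluster.member_ids:
            ref = by_id.get(member)
            if ref is None:
                continue
            if ref.body_site_broad:
                cluster.member_body_sites.add(ref.body_site_broad)
            if ref.source_db == "SEQUENCED_GENOME":
                cluster.contains_sequenced_genome = True
                if ref.body_site_broad:
                    cluster.sequenced_genome_body_sites.add(ref.body_site_broad)


def assign_from_hits(
    hits: Sequence[AlignmentHit],
    clusters: Sequence[Cluster],
    id_threshold: float = 0.99,
    cov_threshold: float = 0.95,
) -> str:
    """Cluster for one query given its hits against the representatives."""
    rep_to_cluster = {c.representative_id: c.cluster_id for c in clusters}
    best_cluster = UNCLUSTERED
    best_key: tuple[float, float] | None = None
    for hit in hits:
        if hit is None or hit.subject_id not in rep_to_cluster:
            continue
        if _passes(hit, id_threshold, cov_threshold):
            key = (hit.pct_identity, hit.query_coverage)
            if best_key is None or key > best_key:
                best_key = key
                best_cluster = rep_to_cluster[hit.subject_id]
    return best_cluster


def assign_to_representatives(
    queries: Sequence[tuple[str, str]],
    clusters: Sequence[Cluster],
    representative_seqs: Mapping[str, str],
    id_threshold: float = 0.99,
    cov_threshold: float = 0.95,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> dict[str, str]:
    """Assign each query to the best-matching cluster representative.

    Returns ``query_id -> cluster_id`` with :data:`UNCLUSTERED` for queries
    passing both thresholds against no representative. Reference clusters
    are not modified.
    """
    out: dict[str, str] = {}
    for qid, qseq in queries:
        hits = [
            align_pair(qseq, representative_seqs[c.representative_id], qid, c.representative_id, scoring)
            for c in clusters
        ]
        out[qid] = assign_from_hits(hits, clusters, id_threshold, cov_threshold)
    return out


def write_clusters_tsv(
    clusters: Sequence[Cluster],
    sequences: Mapping[str, str],
    path: str | Path,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["cluster_id", "representative_id", "member_id", "member_length", "pident_to_rep", "qcov_to_rep"]
        )
        for c in clusters:
            rep_seq = sequences[c.representative_id]
            for m in c.member_ids:
                if m == c.representative_id:
                    pident, qcov = 100.0, 100.0
                else:
                    hit = align_pair(sequences[m], rep_seq, m, c.representative_id, scoring)
                    pident = hit.pct_identity if hit else 0.0
                    qcov = hit.query_coverage if hit else 0.0
                writer.writerow(
                    [c.cluster_id, c.representative_id, m, len(sequences[m]), f"{pident:.3f}", f"{qcov:.3f}"]
                )
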