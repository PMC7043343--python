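"""Novelty classification of query 16S samples.

Two rules, applied to one representative replicate per post-QC sample:

* novel by similarity — the best database hit has <=97% identity and/or
  <=90% query coverage (or there is no hit at all);
* novel by phylogeny — the sample's cluster contains no sequenced-genome
  16S, or every sequenced co-member was isolated from a different broad
  body site.

NOVEL takes precedence over NOVEL_BY_PHYLOGENY; everything else is KNOWN.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .clustering import UNCLUSTERED, Cluster
from .sequence_core import AlignmentHit, SeqRecord16S

NOVEL = "NOVEL"
NOVEL_BY_PHYLOGENY = "NOVEL_BY_PHYLOGENY"
KNOWN = "KNOWN"


@dataclass
class NoveltyCall:
    sample_id: str
    status: str
    best_hit: AlignmentHit | None
    cluster_id: str
    reason: str


def classify_by_similarity(
    best_hit: AlignmentHit | None, id_cut: float = 97.0, cov_cut: float = 90.0
) -> bool:
    """True iff the sample is novel by similarity (thresholds inclusive)."""
    if best_hit is None:
        return True
    return best_hit.pct_identity <= id_cut or best_hit.query_coverage <= cov_cut


def classify_by_phylogeny(
    cluster_id: str,
    clusters: Mapping[str, Cluster],
    body_site_broad: str,
) -> bool:
    """True iff no sequenced-genome co-member shares the sample's body site.

    Unclustered samples are novel by phylogeny (no sequenced co-member at
    all). Clusters must be annotated with sequenced-genome membership and
    the body sites of their sequenced members.
    """
    if cluster_id == UNCLUSTERED:
        return True
    cluster = clusters[cluster_id]
    if not cluster.contains_sequenced_genome:
        return True
    return body_site_broad not in cluster.sequenced_genome_body_sites


def call_novelty(
    samples: Sequence[SeqRecord16S],
    hits: Mapping[str, AlignmentHit | None],
    assignments: Mapping[str, str],
    clusters: Mapping[str, Cluster],
    id_cut: float = 97.0,
    cov_cut: float = 90.0,
) -> list[NoveltyCall]:
    """One NoveltyCall per sample, precedence NOVEL > NOVEL_BY_PHYLOGENY > KNOWN."""
    calls = []
    for sample in samples:
        sid = sample.sample_id
        if sid not in hits or sid not in assignments:
            warnings.warn(f"sample {sid} has no hit/assignment record; excluded")
            continue
        hit = hits[sid]
        cluster_id = assignments[sid]
        if classify_by_similarity(hit, id_cut, cov_cut):
            status = NOVEL
            if hit is None:
                reason = "no database hit"
            else:
                reason = (
                    f"best hit {hit.subject_id}: {hit.pct_identity:.2f}% id, "
                    f"{hit.query_coverage:.2f}% cov below novelty cutoffs"
                )
        elif classify_by_phylogeny(cluster_id, clusters, sample.body_site_broad):
            status = NOVEL_BY_PHYLOGENY
            if cluster_id == UNCLUSTERED:
                reason = "clusters with no sequenced genome"
            elif not clusters[cluster_id].contains_sequenced_genome:
                reason = f"cluster {cluster_id} has no sequenced-genome member"
            else:
                reason = (
                    f"body site {sample.body_site_broad} differs from sequenced "
                    f"co-members ({', '.join(sorted(clusters[cluster_id].sequenced_genome_body_sites))})"
                )
        else:
            status = KNOWN
            reason = f"matches sequenced genome in cluster {cluster_id} from the same body site"
        calls.append(NoveltyCall(sid, status, hit, cluster_id, reason))
    return calls


def status_counts(calls: Sequence[NoveltyCall]) -> dict[str, int]:
    counts = {NOVEL: 0, NOVEL_BY_PHYLOGENY: 0, KNOWN: 0}
    for c in calls:
        counts[c.status] += 1
    return counts


def write_novelty_tsv(calls: Sequence[NoveltyCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "status", "best_hit_ref", "pident", "qcov", "cluster_id", "reason"])
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.status,
                    c.best_hit.subject_id if c.best_hit else "",
                    f"{c.best_hit.pct_identity:.3f}" if c.best_hit else "",
                    f"{c.best_hit.query_coverage:.3f}" if c.best_hit else "",
                    c.cluster_id,
                    c.reason,
                ]
            )
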