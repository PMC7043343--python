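"""Six-tier sequencing prioritization of post-QC samples.

Tiers, in selection order:

1. all novel-by-similarity samples;
2. the top-ranked novel-by-phylogeny member of each cluster containing one;
3. top representatives of all-known clusters;
4. non-top novel-by-phylogeny samples from an isolation source unique
   within their cluster, capped per cluster;
5. remaining novel-by-phylogeny samples, ordered by within-cluster rank
   and body-site desirability/rarity;
6. known samples whose isolation source is unique within their cluster.

Within a cluster, samples are ranked novelty-first: ascending best-hit
identity with no-hit samples first, ties broken by descending length then
sample id. Unclustered samples form singleton pseudo-clusters.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .clustering import UNCLUSTERED
from .novelty import KNOWN, NOVEL, NOVEL_BY_PHYLOGENY, NoveltyCall
from .sequence_core import AlignmentHit

DEFAULT_DESIRABLE_SITES = ["Blood", "Peritoneal fluid", "Wound", "Joint", "Bone"]


@dataclass
class RankingConfig:
    per_cluster_cap_tier4: int = 5
    desirable_sites: list[str] = field(default_factory=lambda: list(DEFAULT_DESIRABLE_SITES))
    rarity_weighting: bool = True
    uniqueness_scope: str = "cluster"

    def __post_init__(self) -> None:
        if self.per_cluster_cap_tier4 < 1:
            raise ValueError("per_cluster_cap_tier4 must be >= 1")


@dataclass
class PriorityAssignment:
    sample_id: str
    tier: int | None  # None = fits no tier
    within_tier_rank: int
    cluster_id: str
    novelty_status: str
    body_site_broad: str
    selected: bool = False


@dataclass
class _Member:
    sample_id: str
    status: str
    cluster_id: str
    body_site: str
    identity: float | None
    length: int
    rank: int = 0  # within-cluster rank, 1-based

    @property
    def novelty_key(self) -> tuple:
        # no-hit first, then most divergent, then longest, then id
        return (
            0 if self.identity is None else 1,
            self.identity if self.identity is not None else 0.0,
            -self.length,
            self.sample_id,
        )


def rank_within_cluster(
    members: Sequence[tuple[str, float | None, int]],
) -> list[str]:
    """Order cluster members novelty-first.

    ``members`` are ``(sample_id, best_hit_identity_or_None, length)``;
    no-hit members sort first, then ascending identity, descending length,
    lexicographic id.
    """
    return [
        m[0]
        for m in sorted(
            members,
            key=lambda m: (0 if m[1] is None else 1, m[1] if m[1] is not None else 0.0, -m[2], m[0]),
        )
    ]


def _build_members(
    calls: Sequence[NoveltyCall],
    lengths: Mapping[str, int],
    body_sites: Mapping[str, str],
) -> list[_Member]:
    members = []
    for call in calls:
        if call.sample_id not in lengths or call.sample_id not in body_sites:
            raise ValueError(f"inconsistent inputs: no length/body site for sample {call.sample_id}")
        cluster = call.cluster_id
        if cluster == UNCLUSTERED:
            cluster = f"{UNCLUSTERED}.{call.sample_id}"
        members.append(
            _Member(
                sample_id=call.sample_id,
                status=call.status,
                cluster_id=cluster,
                body_site=body_sites[call.sample_id],
                identity=call.best_hit.pct_identity if call.best_hit else None,
                length=lengths[call.sample_id],
            )
        )
    return members


def assign_tiers(
    calls: Sequence[NoveltyCall],
    lengths: Mapping[str, int],
    body_sites: Mapping[str, str],
    config: RankingConfig | None = None,
) -> list[PriorityAssignment]:
    """Assign every sample to one of the six priority tiers (or none).

    Deterministic in input order: all orderings are canonicalized through
    the novelty-first ranking key.
    """
    config = config or RankingConfig()
    members = _build_members(calls, lengths, body_sites)

    by_cluster: dict[str, list[_Member]] = {}
    for m in members:
        by_cluster.setdefault(m.cluster_id, []).append(m)
    for cluster_members in by_cluster.values():
        order = rank_within_cluster(
            [(m.sample_id, m.identity, m.length) for m in cluster_members]
        )
        pos = {sid: i + 1 for i, sid in enumerate(order)}
        for m in cluster_members:
            m.rank = pos[m.sample_id]

    tier_of: dict[str, int] = {}

    # tier 1: all novel-by-similarity samples
    tier1 = sorted((m for m in members if m.status == NOVEL), key=lambda m: m.novelty_key)
    for m in tier1:
        tier_of[m.sample_id] = 1

    # tier 2: top-ranked novel-by-phylogeny member per cluster containing one
    tier2 = []
    for cluster_id in sorted(by_cluster):
        nbp = [m for m in by_cluster[cluster_id] if m.status == NOVEL_BY_PHYLOGENY]
        if nbp:
            tier2.append(min(nbp, key=lambda m: m.rank))
    tier2.sort(key=lambda m: m.novelty_key)
    for m in tier2:
        tier_of[m.sample_id] = 2

    # tier 3: top representative of each all-known cluster
    tier3 = []
    for cluster_id in sorted(by_cluster):
        cluster_members = by_cluster[cluster_id]
        if all(m.status == KNOWN for m in cluster_members):
            tier3.append(min(cluster_members, key=lambda m: m.rank))
    tier3.sort(key=lambda m: m.novelty_key)
    for m in tier3:
        tier_of[m.sample_id] = 3

    # tier 4: non-top novel-by-phylogeny from a cluster-unique isolation
    # source, up to the per-cluster cap
    tier4 = []
    for cluster_id in sorted(by_cluster):
        cluster_members = by_cluster[cluster_id]
        site_counts = Counter(m.body_site for m in cluster_members)
        candidates = [
            m
            for m in cluster_members
            if m.status == NOVEL_BY_PHYLOGENY
            and m.sample_id not in tier_of
            and site_counts[m.body_site] == 1
        ]
        candidates.sort(key=lambda m: m.rank)
        tier4.extend(candidates[: config.per_cluster_cap_tier4])
    tier4.sort(key=lambda m: (m.rank, m.novelty_key))
    for m in tier4:
        tier_of[m.sample_id] = 4

    # tier 5: remaining novel-by-phylogeny, by within-cluster rank then
    # body-site desirability (list order) then rarity among candidates
    tier5 = [m for m in members if m.status == NOVEL_BY_PHYLOGENY and m.sample_id not in tier_of]
    site_freq = Counter(m.body_site for m in tier5)
    desirable_index = {site: i for i, site in enumerate(config.desirable_sites)}

    def _tier5_key(m: _Member) -> tuple:
        return (
            m.rank,
            desirable_index.get(m.body_site, len(config.desirable_sites)),
            site_freq[m.body_site] if config.rarity_weighting else 0,
            m.sample_id,
        )

    tier5.sort(key=_tier5_key)
    for m in tier5:
        tier_of[m.sample_id] = 5

    # tier 6: known samples from a cluster-unique isolation source
    tier6 = []
    for cluster_id in sorted(by_cluster):
        cluster_members = by_cluster[cluster_id]
        site_counts = Counter(m.body_site for m in cluster_members)
        tier6.extend(
            m
            for m in cluster_members
            if m.status == KNOWN and m.sample_id not in tier_of and site_counts[m.body_site] == 1
        )
    tier6.sort(key=lambda m: m.novelty_key)
    for m in tier6:
        tier_of[m.sample_id] = 6

    tier_lists = {1: tier1, 2: tier2, 3: tier3, 4: tier4, 5: tier5, 6: tier6}
    assignments = []
    assigned_ids = set()
    for tier, tier_members in tier_lists.items():
        for i, m in enumerate(tier_members, start=1):
            assignments.append(
                PriorityAssignment(
                    sample_id=m.sample_id,
                    tier=tier,
                    within_tier_rank=i,
                    cluster_id=m.cluster_id,
                    novelty_status=m.status,
                    body_site_broad=m.body_site,
                )
            )
            assigned_ids.add(m.sample_id)
    for m in sorted(members, key=lambda m: m.sample_id):
        if m.sample_id not in assigned_ids:
            assignments.append(
                PriorityAssignment(
                    sample_id=m.sample_id,
                    tier=None,
                    within_tier_rank=0,
                    cluster_id=m.cluster_id,
                    novelty_status=m.status,
                    body_site_broad=m.body_site,
                )
            )
    return assignments


def select_top_n(
    assignments: Sequence[PriorityAssignment],
    n: int,
    unavailable: set[str] | frozenset[str] = frozenset(),
) -> list[PriorityAssignment]:
    """Final prioritized list: tiers 1→6, within tier by rank, length n.

    Samples in ``unavailable`` are skipped without consuming a slot. Marks
    ``selected`` on the chosen assignments.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    ordered = sorted(
        (a for a in assignments if a.tier is not None),
        key=lambda a: (a.tier, a.within_tier_rank),
    )
    selection = []
    for a in ordered:
        if len(selection) >= n:
            break
        if a.sample_id in unavailable:
            continue
        a.selected = True
        selection.append(a)
    if n > len(selection) and n > 0:
        warnings.warn(
            f"requested {n} samples but only {len(selection)} are assigned and available"
        )
    return selection


def write_priority_tsv(selection: Sequence[PriorityAssignment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["rank", "sample_id", "tier", "within_tier_rank", "cluster_id", "novelty_status", "body_site_broad"]
        )
        for i, a in enumerate(selection, start=1):
            writer.writerow(
                [i, a.sample_id, a.tier, a.within_tier_rank, a.cluster_id, a.novelty_status, a.body_site_broad]
            )
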