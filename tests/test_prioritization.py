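"""Tier assignment and ranked selection."""

import numpy as np
import pytest

from strainprio.clustering import UNCLUSTERED
from strainprio.novelty import KNOWN, NOVEL, NOVEL_BY_PHYLOGENY, NoveltyCall
from strainprio.prioritization import (
    PriorityAssignment,
    RankingConfig,
    assign_tiers,
    rank_within_cluster,
    select_top_n,
)
from strainprio.sequence_core import AlignmentHit
from strainprio.synthetic import expected_tiers

L = 1500


def _hit(pident, subject="R1"):
    return AlignmentHit("q", subject, pident, 100.0, L, 1, L, 1, L, 2.0 * L)


def _call(sid, status, cluster, pident=None):
    return NoveltyCall(
        sample_id=sid,
        status=status,
        best_hit=None if pident is None else _hit(pident),
        cluster_id=cluster,
        reason="",
    )


class TestRankWithinCluster:
    def test_singleton(self):
        assert rank_within_cluster([("a", 99.0, L)]) == ["a"]

    def test_no_hit_first_then_ascending_identity(self):
        members = [("a", 99.5, L), ("b", 97.2, L), ("c", None, L)]
        assert rank_within_cluster(members) == ["c", "b", "a"]

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            members = [
                (
                    f"s{i}",
                    None if rng.random() < 0.2 else float(rng.uniform(90, 100)),
                    int(rng.integers(1200, 1600)),
                )
                for i in range(int(rng.integers(1, 12)))
            ]
            expected = sorted(
                members,
                key=lambda m: (m[1] is not None, m[1] if m[1] is not None else 0.0, -m[2], m[0]),
            )
            assert rank_within_cluster(members) == [m[0] for m in expected]


class TestAssignTiers:
    def _run(self, calls, sites=None, config=None):
        lengths = {c.sample_id: L for c in calls}
        sites = sites or {c.sample_id: "Skin" for c in calls}
        return assign_tiers(calls, lengths, sites, config)

    def test_all_novel_collection_is_all_tier_one(self):
        calls = [_call(f"S{i}", NOVEL, UNCLUSTERED, 94.0 + i * 0.1) for i in range(5)]
        tiers = self._run(calls)
        assert all(a.tier == 1 for a in tiers)
        # within-tier order follows ascending best-hit identity
        ordered = sorted(tiers, key=lambda a: a.within_tier_rank)
        assert [a.sample_id for a in ordered] == [f"S{i}" for i in range(5)]

    def test_tier4_cap_with_unique_sites(self):
        """A cluster with 9 unique-site non-top members feeds tier 4 at most 5."""
        sites = {}
        calls = []
        for i in range(10):
            sid = f"S{i}"
            calls.append(_call(sid, NOVEL_BY_PHYLOGENY, "C1", 99.0 + i * 0.05))
            sites[sid] = f"Site{i}"  # all unique within the cluster
        tiers = self._run(calls, sites)
        by_tier = {}
        for a in tiers:
            by_tier.setdefault(a.tier, []).append(a)
        assert len(by_tier[2]) == 1  # top of the cluster
        assert len(by_tier[4]) == 5  # capped
        assert len(by_tier[5]) == 4  # remainder

    def test_same_site_nonunique_members_fall_to_tier5(self):
        sites = {f"S{i}": "Skin" for i in range(9)}
        calls = [_call(f"S{i}", NOVEL_BY_PHYLOGENY, "C1", 99.0 + i * 0.05) for i in range(9)]
        tiers = self._run(calls, sites)
        n_tier4 = sum(1 for a in tiers if a.tier == 4)
        assert n_tier4 <= 5 and n_tier4 == 0  # shared site is never unique

    def test_known_unique_source_reaches_tier6(self):
        sites = {"S0": "Skin", "S1": "Skin", "S2": "Blood"}
        calls = [_call(f"S{i}", KNOWN, "C1", 99.8) for i in range(3)]
        tiers = {a.sample_id: a.tier for a in self._run(calls, sites)}
        # one sample tops the all-known cluster (tier 3); the unique-source
        # non-top member lands in tier 6; the shared-site one is unassigned
        assert sorted(tiers.values(), key=str) == sorted([3, 6, None], key=str)
        assert tiers["S2"] in (3, 6)

    def test_tier5_prefers_desirable_then_rare_sites(self):
        # sites repeat within each cluster so nothing qualifies for tier 4
        spec = [
            # (sample, cluster, identity, site)
            ("T0", "C1", 98.0, "Skin"),
            ("S0", "C1", 99.00, "Skin"),
            ("S2", "C1", 99.20, "Skin"),
            ("S6", "C1", 99.40, "Skin"),
            ("T1", "C2", 98.1, "Blood"),
            ("S1", "C2", 99.10, "Blood"),
            ("S4", "C2", 99.30, "Blood"),
            ("T2", "C3", 98.2, "Eye"),
            ("S3", "C3", 99.15, "Eye"),
            ("S5", "C3", 99.25, "Eye"),
        ]
        calls = [_call(sid, NOVEL_BY_PHYLOGENY, c, pid) for sid, c, pid, _ in spec]
        sites = {sid: site for sid, _, _, site in spec}
        tiers = self._run(calls, sites)
        tier5 = sorted((a for a in tiers if a.tier == 5), key=lambda a: a.within_tier_rank)
        ids = [a.sample_id for a in tier5]
        # within each within-cluster rank: Blood (desirable list) first, then
        # the rarer Eye (2 candidates) before Skin (3 candidates)
        assert ids == ["S1", "S3", "S0", "S4", "S5", "S2", "S6"]

    def test_partition_and_tier_order(self):
        rng = np.random.default_rng(11)
        calls, sites = _random_scenario(rng)
        tiers = self._run(calls, sites)
        assert sorted(a.sample_id for a in tiers) == sorted(c.sample_id for c in calls)
        for tier_members in _group_by_tier(tiers).values():
            ranks = sorted(a.within_tier_rank for a in tier_members)
            assert ranks == list(range(1, len(ranks) + 1))

    def test_deterministic_under_permutation(self):
        rng = np.random.default_rng(12)
        calls, sites = _random_scenario(rng)
        tiers_a = self._run(calls, sites)
        shuffled = list(calls)
        rng.shuffle(shuffled)
        tiers_b = self._run(shuffled, sites)
        key = lambda a: (a.sample_id, a.tier, a.within_tier_rank)
        assert sorted(map(key, tiers_a)) == sorted(map(key, tiers_b))

    def test_inconsistent_inputs_name_the_sample(self):
        calls = [_call("S1", KNOWN, "C1", 99.8)]
        with pytest.raises(ValueError, match="S1"):
            assign_tiers(calls, {}, {"S1": "Skin"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_straight_line_tier_oracle(self, seed):
        """Random planted scenarios: assign_tiers agrees with the
        independent transcription of the tier rules."""
        rng = np.random.default_rng(200 + seed)
        truth = {}
        calls, sites = [], {}
        n = int(rng.integers(15, 40))
        site_pool = ["Skin", "Blood", "Respiratory", "Bone", "Wound", "Eye"]
        for i in range(n):
            sid = f"S{i:03d}"
            cat = [KNOWN, NOVEL, NOVEL_BY_PHYLOGENY][int(rng.integers(0, 3))]
            ref = f"R{int(rng.integers(0, 6))}"
            k = {
                KNOWN: int(rng.integers(1, 5)),
                NOVEL_BY_PHYLOGENY: int(rng.integers(6, 10)),
                NOVEL: int(rng.integers(75, 106)),
            }[cat]
            site = site_pool[int(rng.integers(0, len(site_pool)))]
            truth[sid] = {
                "category": cat,
                "source_refs": [ref],
                "body_site_broad": site,
                "k_rep": k,
            }
            cluster = UNCLUSTERED if cat == NOVEL else ref
            calls.append(_call(sid, cat, cluster, 100.0 * (L - k) / L))
            sites[sid] = site
        oracle = expected_tiers(truth)
        tiers = {a.sample_id: a.tier for a in self._run(calls, sites)}
        assert tiers == oracle


class TestSelectTopN:
    def _assignments(self, tier_sizes):
        out = []
        for tier, size in enumerate(tier_sizes, start=1):
            for rank in range(1, size + 1):
                out.append(
                    PriorityAssignment(
                        sample_id=f"T{tier}R{rank:04d}",
                        tier=tier,
                        within_tier_rank=rank,
                        cluster_id="C1",
                        novelty_status=KNOWN,
                        body_site_broad="Skin",
                    )
                )
        return out

    def test_zero_selects_nothing(self):
        assert select_top_n(self._assignments([3, 2]), 0) == []

    def test_n_beyond_total_returns_all_with_warning(self):
        assignments = self._assignments([3, 2])
        with pytest.warns(UserWarning):
            out = select_top_n(assignments, 10)
        assert len(out) == 5

    def test_tier_order_respected(self):
        out = select_top_n(self._assignments([2, 2, 2]), 5)
        assert [a.tier for a in out] == [1, 1, 2, 2, 3]

    def test_unavailable_samples_skipped_without_consuming_slots(self):
        assignments = self._assignments([3])
        out = select_top_n(assignments, 2, unavailable={"T1R0001"})
        assert [a.sample_id for a in out] == ["T1R0002", "T1R0003"]

    def test_prefix_property(self):
        assignments = self._assignments([4, 3, 2])
        short = [a.sample_id for a in select_top_n(assignments, 5)]
        longer = [a.sample_id for a in select_top_n(assignments, 6)]
        assert longer[:5] == short


def _random_scenario(rng):
    calls, sites = [], {}
    site_pool = ["Skin", "Blood", "Respiratory", "Bone"]
    for i in range(25):
        sid = f"S{i:03d}"
        cat = [KNOWN, NOVEL, NOVEL_BY_PHYLOGENY][int(rng.integers(0, 3))]
        cluster = UNCLUSTERED if cat == NOVEL else f"C{int(rng.integers(0, 5))}"
        pident = float(rng.uniform(94, 96)) if cat == NOVEL else float(rng.uniform(99, 100))
        calls.append(_call(sid, cat, cluster, pident))
        sites[sid] = site_pool[int(rng.integers(0, len(site_pool)))]
    return calls, sites


def _group_by_tier(assignments):
    out = {}
    for a in assignments:
        if a.tier is not None:
            out.setdefault(a.tier, []).append(a)
    return out
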