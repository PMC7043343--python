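"""Contamination screening and body-site harmonization.

Two independent contamination rules:

* replicate conflict — technical replicates of one cultured sample landing
  in different 16S clusters imply a mixed culture;
* genus conflict — assembly supercontigs of one strain whose top database
  hits name two different genera.

Body-site harmonization collapses free-text isolation sources ("abscess,
arm") into the broad habitat categories every downstream comparison uses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .clustering import UNCLUSTERED
from .sequence_core import DEFAULT_SCORING, AlignmentScoring, SeqRecord16S, align_pair


@dataclass
class ContaminationReport:
    sample_id: str
    contaminated: bool
    evidence: list[tuple[str, str]]  # (replicate_id or contig_id, cluster/genus label)
    rule: str  # REPLICATE_CONFLICT or GENUS_CONFLICT


def _pseudo_labels(
    unclustered: Sequence[SeqRecord16S],
    id_threshold: float,
    cov_threshold: float,
    scoring: AlignmentScoring,
) -> dict[str, str]:
    """Group a sample's unclustered replicates that would cluster together.

    Each connected component (at the clustering thresholds) gets one
    pseudo-label, so two unclustered replicates of a genuinely novel strain
    do not count as conflicting.
    """
    parent = {r.replicate_id: r.replicate_id for r in unclustered}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(unclustered):
        for b in unclustered[i + 1 :]:
            hit = align_pair(a.sequence, b.sequence, a.replicate_id, b.replicate_id, scoring)
            if (
                hit is not None
                and hit.pct_identity >= 100.0 * id_threshold
                and hit.query_coverage >= 100.0 * cov_threshold
            ):
                parent[find(a.replicate_id)] = find(b.replicate_id)
    comp: dict[str, list[str]] = {}
    for r in unclustered:
        comp.setdefault(find(r.replicate_id), []).append(r.replicate_id)
    labels: dict[str, str] = {}
    for reps in comp.values():
        tag = f"{UNCLUSTERED}.{min(reps)}"
        for rid in reps:
            labels[rid] = tag
    return labels


def detect_replicate_conflicts(
    records: Sequence[SeqRecord16S],
    assignments: Mapping[str, str],
    id_threshold: float = 0.99,
    cov_threshold: float = 0.95,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[ContaminationReport]:
    """Flag samples whose replicates fall in distinct clusters.

    ``assignments`` maps record ids (``sample.replicate``) to cluster ids,
    with :data:`UNCLUSTERED` for replicates matching no representative.
    A sample is contaminated iff its replicates carry >= 2 distinct cluster
    labels; single-replicate samples can never be flagged.
    """
    by_sample: dict[str, list[SeqRecord16S]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    reports = []
    for sample_id in sorted(by_sample):
        replicates = by_sample[sample_id]
        unclustered = [r for r in replicates if assignments[r.record_id] == UNCLUSTERED]
        pseudo = _pseudo_labels(unclustered, id_threshold, cov_threshold, scoring)
        evidence = []
        for r in sorted(replicates, key=lambda r: r.replicate_id):
            label = assignments[r.record_id]
            if label == UNCLUSTERED:
                label = pseudo[r.replicate_id]
            evidence.append((r.replicate_id, label))
        distinct = {label for _, label in evidence}
        reports.append(
            ContaminationReport(
                sample_id=sample_id,
                contaminated=len(distinct) >= 2,
                evidence=evidence,
                rule="REPLICATE_CONFLICT",
            )
        )
    return reports


def choose_representative_replicates(
    records: Sequence[SeqRecord16S], reports: Sequence[ContaminationReport]
) -> list[SeqRecord16S]:
    """One representative replicate per clean sample: longest, ties on id."""
    contaminated = {r.sample_id for r in reports if r.contaminated}
    by_sample: dict[str, list[SeqRecord16S]] = {}
    for rec in records:
        if rec.sample_id not in contaminated:
            by_sample.setdefault(rec.sample_id, []).append(rec)
    return [
        min(reps, key=lambda r: (-r.length, r.replicate_id))
        for _, reps in sorted(by_sample.items())
    ]


def detect_genus_conflicts(
    contig_top_genus: Iterable[tuple[str, str, str | None]],
) -> list[ContaminationReport]:
    """Flag strains whose supercontigs hit >= 2 distinct top genera.

    Input rows are ``(contig_id, strain_id, top_genus)``; contigs with no
    hit (``top_genus`` None or empty) are ignored.
    """
    by_strain: dict[str, list[tuple[str, str]]] = {}
    for contig_id, strain_id, genus in contig_top_genus:
        by_strain.setdefault(strain_id, [])
        if genus:
            by_strain[strain_id].append((contig_id, genus))
    return [
        ContaminationReport(
            sample_id=strain_id,
            contaminated=len({g for _, g in ev}) >= 2,
            evidence=ev,
            rule="GENUS_CONFLICT",
        )
        for strain_id, ev in sorted(by_strain.items())
    ]


# ---------------------------------------------------------------------------
# Body-site collapsing


def load_body_site_map(path: str | Path | None = None) -> list[tuple[str, str]]:
    """Load the detailed-site → broad-category table (default shipped TSV)."""
    if path is None:
        source = resources.files("strainprio").joinpath("data/body_sites.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    return [(pat.lower(), broad) for pat, broad in rows[1:] if pat]


_default_map: list[tuple[str, str]] | None = None


def collapse_body_site(
    detailed_site: str, mapping: Sequence[tuple[str, str]] | None = None
) -> str:
    """Collapse a detailed isolation source into its broad habitat category.

    Case-insensitive; among patterns occurring as a substring of the
    detailed site, the longest (most specific) wins; patterns anchored at
    the start take precedence over interior matches. Unmatched → "Unknown".
    """
    global _default_map
    if mapping is None:
        if _default_map is None:
            _default_map = load_body_site_map()
        mapping = _default_map
    site = detailed_site.strip().lower()
    if not site:
        return "Unknown"
    best: tuple[int, int, str] | None = None  # (prefix?, pattern length, category)
    for pattern, broad in mapping:
        idx = site.find(pattern)
        if idx < 0:
            continue
        key = (1 if idx == 0 else 0, len(pattern), broad)
        if best is None or key > best:
            best = key
    return best[2] if best else "Unknown"


def write_contamination_tsv(reports: Sequence[ContaminationReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "contaminated", "rule", "evidence"])
        for r in reports:
            ev = ";".join(f"{a}:{b}" for a, b in r.evidence)
            writer.writerow([r.sample_id, int(r.contaminated), r.rule, ev])
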