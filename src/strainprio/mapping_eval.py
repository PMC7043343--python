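"""Database-augmentation evaluation from read alignments.

Quantifies what a set of newly sequenced genomes adds to a baseline genome
database: per-sample mapped-read counts against both databases, per-genome
coverage breadth/depth, high-representation calls, grouped improvement
tables, and a hypergeometric enrichment test for high-representation
genomes among the new set.

Read mapping itself is consumed, not performed: the module ingests SAM
from any mapper and uses primary mapped alignments only.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from scipy.stats import hypergeom


@dataclass
class CoverageProfile:
    genome_id: str
    genome_length: int
    breadth: float  # fraction of positions covered by >= 1 read
    mean_depth: float  # aligned bases / genome length
    n_reads: int


@dataclass
class MappingSummary:
    sample_id: str
    body_site: str
    n_cleaned_reads: int
    n_mapped_baseline: int
    n_mapped_augmented: int
    per_phylum_mapped: dict[str, tuple[int, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Read cleaning


def _clean_one(seq: str, quals: Sequence[int], qual_floor: int = 2, min_run: int = 60):
    """Trim Q<=floor tails from both ends; drop if longest non-N run < min_run."""
    start = 0
    while start < len(quals) and quals[start] <= qual_floor:
        start += 1
    end = len(quals)
    while end > start and quals[end - 1] <= qual_floor:
        end -= 1
    trimmed_seq = seq[start:end]
    trimmed_quals = list(quals[start:end])
    longest = run = 0
    for base in trimmed_seq:
        run = 0 if base == "N" else run + 1
        longest = max(longest, run)
    keep = longest >= min_run
    return keep, trimmed_seq, trimmed_quals, start, len(seq) - end


def clean_reads(
    fastq_path: str | Path,
    out_path: str | Path | None = None,
    qual_floor: int = 2,
    min_nonn_run: int = 60,
) -> tuple[list[tuple[str, str, list[int]]], dict[str, int]]:
    """Quality-clean a FASTQ file.

    Trims maximal runs of quality <= ``qual_floor`` from both read ends,
    then drops reads whose longest run of consecutive non-N bases is below
    ``min_nonn_run``. Returns the surviving ``(read_id, seq, quals)``
    records and kept/dropped counts; optionally writes the cleaned FASTQ.
    """
    kept: list[tuple[str, str, list[int]]] = []
    n_in = 0
    try:
        for i, rec in enumerate(SeqIO.parse(str(fastq_path), "fastq")):
            n_in += 1
            quals = rec.letter_annotations["phred_quality"]
            ok, seq, tq, _, _ = _clean_one(str(rec.seq), quals, qual_floor, min_nonn_run)
            if ok:
                kept.append((rec.id, seq, tq))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record index {n_in}: {exc}") from exc
    if out_path is not None:
        with open(out_path, "w") as fh:
            for rid, seq, quals in kept:
                qstr = "".join(chr(q + 33) for q in quals)
                fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")
    return kept, {"input": n_in, "kept": len(kept), "dropped": n_in - len(kept)}


# ---------------------------------------------------------------------------
# Sample outlier filtering


def filter_sample_outliers(
    read_counts: Mapping[str, int],
    body_sites: Mapping[str, str],
    lower_quantile: float = 0.05,
    sd_multiplier: float = 3.0,
) -> list[str]:
    """Drop per-body-site read-count outliers.

    First drops samples strictly above mean + ``sd_multiplier``·SD of their
    body site (computed once, on all of the site's samples; skipped for
    sites with < 2 samples), then the ``floor(lower_quantile · n)`` smallest
    samples per site. Returns retained sample ids, sorted.
    """
    by_site: dict[str, list[str]] = {}
    for sid in read_counts:
        by_site.setdefault(body_sites[sid], []).append(sid)
    retained: list[str] = []
    for site in sorted(by_site):
        sids = by_site[site]
        counts = np.array([read_counts[s] for s in sids], dtype=float)
        if len(sids) >= 2:
            upper = counts.mean() + sd_multiplier * counts.std(ddof=0)
            survivors = [s for s in sids if read_counts[s] <= upper]
        else:
            survivors = list(sids)
        n_drop = math.floor(lower_quantile * len(survivors))
        if n_drop > 0:
            # smallest first; ties broken on sample id for determinism
            ordered = sorted(survivors, key=lambda s: (read_counts[s], s))
            survivors = ordered[n_drop:]
        retained.extend(survivors)
    return sorted(retained)


# ---------------------------------------------------------------------------
# Coverage from SAM


def _reference_blocks(aln: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Reference intervals covered by aligned read bases (M/=/X only)."""
    blocks = []
    pos = aln.reference_start
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X
            blocks.append((pos, pos + length))
            pos += length
        elif op in (2, 3):  # D, N consume reference but carry no read base
            pos += length
    return blocks


def _iter_primary(sam_path: str | Path):
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        lengths = dict(zip(sam.references, sam.lengths))
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            yield aln, lengths


def coverage_profiles(
    sam_path: str | Path, genome_lengths: Mapping[str, int] | None = None
) -> list[CoverageProfile]:
    """Per-genome breadth and mean depth from primary SAM alignments.

    Breadth is the fraction of genome positions under the union of the
    reference intervals covered by aligned read bases; mean depth is total
    aligned bases over genome length. Genome lengths default to the SAM
    @SQ header.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    n_reads: dict[str, int] = {}
    header_lengths: Mapping[str, int] = {}
    for aln, header_lengths in _iter_primary(sam_path):
        gid = aln.reference_name
        if genome_lengths is not None and gid not in genome_lengths:
            raise ValueError(f"alignment references unknown genome {gid}")
        intervals.setdefault(gid, []).extend(_reference_blocks(aln))
        n_reads[gid] = n_reads.get(gid, 0) + 1
    lengths = dict(header_lengths)
    if genome_lengths is not None:
        lengths.update(genome_lengths)
    profiles = []
    for gid in sorted(lengths):
        ivs = sorted(intervals.get(gid, []))
        covered = 0
        total_bases = 0
        cur_start, cur_end = None, None
        for start, end in ivs:
            total_bases += end - start
            if cur_end is None or start > cur_end:
                if cur_end is not None:
                    covered += cur_end - cur_start
                cur_start, cur_end = start, end
            else:
                cur_end = max(cur_end, end)
        if cur_end is not None:
            covered += cur_end - cur_start
        length = lengths[gid]
        profiles.append(
            CoverageProfile(
                genome_id=gid,
                genome_length=length,
                breadth=covered / length,
                mean_depth=total_bases / length,
                n_reads=n_reads.get(gid, 0),
            )
        )
    return profiles


def high_representation(
    profile: CoverageProfile, breadth_cut: float = 0.5, depth_cut: float = 1.0
) -> bool:
    """True iff breadth >= breadth_cut and mean depth >= depth_cut (inclusive)."""
    return profile.breadth >= breadth_cut and profile.mean_depth >= depth_cut


def count_mapped_reads(sam_path: str | Path) -> tuple[int, dict[str, int]]:
    """Primary mapped reads in a SAM: total and per reference genome."""
    per_genome: dict[str, int] = {}
    total = 0
    for aln, _ in _iter_primary(sam_path):
        total += 1
        per_genome[aln.reference_name] = per_genome.get(aln.reference_name, 0) + 1
    return total, per_genome


def summarize_mapping(
    sample_id: str,
    body_site: str,
    n_cleaned_reads: int,
    baseline_sam: str | Path,
    augmented_sam: str | Path,
    genome_phylum: Mapping[str, str] | None = None,
) -> MappingSummary:
    """Per-sample mapped-read counts against baseline and augmented databases."""
    n_base, per_genome_base = count_mapped_reads(baseline_sam)
    n_aug, per_genome_aug = count_mapped_reads(augmented_sam)
    per_phylum: dict[str, tuple[int, int]] = {}
    if genome_phylum is not None:
        phyla = sorted(set(genome_phylum.values()))
        for phylum in phyla:
            base = sum(c for g, c in per_genome_base.items() if genome_phylum.get(g) == phylum)
            aug = sum(c for g, c in per_genome_aug.items() if genome_phylum.get(g) == phylum)
            per_phylum[phylum] = (base, aug)
    return MappingSummary(
        sample_id=sample_id,
        body_site=body_site,
        n_cleaned_reads=n_cleaned_reads,
        n_mapped_baseline=n_base,
        n_mapped_augmented=n_aug,
        per_phylum_mapped=per_phylum,
    )


# ---------------------------------------------------------------------------
# Improvement tables and enrichment


def improvement_summary(
    summaries: Sequence[MappingSummary], group_by: str = "body_site"
) -> pd.DataFrame:
    """Grouped baseline-vs-augmented mapping table.

    ``group_by`` is one of body_site, phylum, sample. Counts are summed
    within groups; ``relative_increase_pct`` = 100·(augmented − baseline)/
    baseline, NaN when the baseline is zero.
    """
    rows = []
    if group_by == "phylum":
        seen = sorted({p for s in summaries for p in s.per_phylum_mapped})
        for phylum in seen:
            base = sum(s.per_phylum_mapped.get(phylum, (0, 0))[0] for s in summaries)
            aug = sum(s.per_phylum_mapped.get(phylum, (0, 0))[1] for s in summaries)
            rows.append((phylum, base, aug))
    elif group_by == "body_site":
        sites = sorted({s.body_site for s in summaries})
        for site in sites:
            base = sum(s.n_mapped_baseline for s in summaries if s.body_site == site)
            aug = sum(s.n_mapped_augmented for s in summaries if s.body_site == site)
            rows.append((site, base, aug))
    elif group_by == "sample":
        for s in sorted(summaries, key=lambda s: s.sample_id):
            rows.append((s.sample_id, s.n_mapped_baseline, s.n_mapped_augmented))
    else:
        raise ValueError(f"unknown group_by: {group_by}")
    df = pd.DataFrame(rows, columns=["group", "baseline", "augmented"])
    df["absolute_increase"] = df["augmented"] - df["baseline"]
    df["relative_increase_pct"] = np.where(
        df["baseline"] > 0, 100.0 * df["absolute_increase"] / df["baseline"], np.nan
    )
    return df


def per_site_report(summaries: Sequence[MappingSummary]) -> pd.DataFrame:
    """Per-body-site averages: sample count, mean cleaned/mapped read counts."""
    df = pd.DataFrame(
        [
            (s.body_site, s.n_cleaned_reads, s.n_mapped_baseline, s.n_mapped_augmented)
            for s in summaries
        ],
        columns=["body_site", "cleaned_reads", "mapped_baseline", "mapped_augmented"],
    )
    out = df.groupby("body_site").agg(
        n_samples=("cleaned_reads", "size"),
        mean_cleaned_reads=("cleaned_reads", "mean"),
        mean_mapped_baseline=("mapped_baseline", "mean"),
        mean_mapped_augmented=("mapped_augmented", "mean"),
    )
    return out.reset_index()


def enrichment_test(
    high_novel: int, total_novel: int, high_public: int, total_public: int
) -> float:
    """One-sided Fisher's exact test for over-representation.

    Tests whether high-representation genomes are enriched among the novel
    set relative to the public set, via the upper hypergeometric tail:
    P(X >= high_novel) with X ~ Hypergeom(N = total_novel + total_public,
    K = high_novel + high_public, n = total_novel).
    """
    if high_novel > total_novel or high_public > total_public:
        raise ValueError("counts exceed totals")
    population = total_novel + total_public
    successes = high_novel + high_public
    return float(hypergeom.sf(high_novel - 1, population, successes, total_novel))


def write_improvement_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4f", na_rep="NA")
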