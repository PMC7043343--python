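"""Synthetic inputs with truth labels for every pipeline stage.

Emulates, at desk scale, the data a targeted strain-prioritization study
consumes: a reference 16S collection (part 16S-only, part tied to
sequenced genomes), a query culture collection with planted known /
novel / novel-by-phylogeny / contaminated samples at controlled
divergences, and shotgun read sets with truth alignments against a
baseline and an augmented genome database.

The mutation model is substitution-only and avoids a conserved margin at
both sequence ends (mimicking conserved primer sites), so the realized
alignment identity of a planted sample is exactly ``(L - k)/L`` for ``k``
substitutions and truth labels can be derived by arithmetic. Planted
divergences sit far from the 97%/99% decision boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from collections import Counter
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam
import yaml

from .sequence_core import (
    ReferenceEntry,
    SeqRecord16S,
    write_fasta_with_metadata,
    write_reference_fasta,
)

BASES = np.array(list("ACGT"))

PHYLA = ["Firmicutes", "Actinobacteria", "Proteobacteria", "Bacteroidetes", "Fusobacteria"]

# detailed isolation source per broad category (collapsible by qc.collapse_body_site)
DETAILED_SITES: dict[str, list[str]] = {
    "Abscess": ["abscess, arm", "abscess, leg"],
    "Skin": ["skin of forearm", "skin fold"],
    "Respiratory": ["sputum", "throat swab"],
    "Urinary tract": ["urine, clean catch"],
    "Blood": ["blood culture"],
    "Bone": ["bone biopsy"],
    "Joint": ["joint fluid"],
    "Peritoneal fluid": ["peritoneal fluid"],
    "Wound": ["wound swab"],
    "Gastrointestinal": ["stool"],
}

DEFAULT_BODY_SITES = list(DETAILED_SITES)

KNOWN = "KNOWN"
NOVEL = "NOVEL"
NOVEL_BY_PHYLOGENY = "NOVEL_BY_PHYLOGENY"
CONTAMINATED = "CONTAMINATED"

# planted substitution-count ranges per category (sequence length 1500):
# KNOWN 1-4 subs (~0.2%), NOVEL_BY_PHYLOGENY 6-9 (~0.5%), NOVEL 75-105 (~6%)
SUB_RANGES = {KNOWN: (1, 4), NOVEL_BY_PHYLOGENY: (6, 9), NOVEL: (75, 105), CONTAMINATED: (1, 4)}

TERMINAL_MARGIN = 20  # bp at each end never mutated (conserved primer sites)


@dataclass
class SimulationConfig:
    seed: int = 1
    n_reference_genomes: int = 10
    sequenced_fraction: float = 0.7
    novel_genome_fraction: float = 0.4
    genome_length_bp: int = 20_000
    gene_16s_length_bp: int = 1500
    n_query_samples: int = 40
    replicates_per_sample: int = 2
    planted_fractions: dict[str, float] = field(
        default_factory=lambda: {KNOWN: 0.45, NOVEL: 0.20, NOVEL_BY_PHYLOGENY: 0.25, CONTAMINATED: 0.10}
    )
    divergence: dict[str, float] = field(
        default_factory=lambda: {KNOWN: 0.002, NOVEL_BY_PHYLOGENY: 0.005, NOVEL: 0.06}
    )
    replicate_noise_rate: float = 0.001
    n_read_samples: int = 6
    read_length: int = 100
    n_reads_per_sample: int = 1200
    read_error_rate: float = 0.005
    lowq_tail_fraction: float = 0.15
    junk_read_fraction: float = 0.05
    unknown_genome_weight: float = 0.10
    body_site_vocabulary: list[str] = field(default_factory=lambda: list(DEFAULT_BODY_SITES))

    def __post_init__(self) -> None:
        total = sum(self.planted_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"planted_fractions sum to {total}, expected 1")
        for cat, d in self.divergence.items():
            if not 0 <= d <= 0.25:
                raise ValueError(f"divergence[{cat}]={d} outside [0, 0.25]")
        if self.read_length > self.genome_length_bp:
            raise ValueError("read_length exceeds genome_length_bp")
        if (
            self.planted_fractions.get(NOVEL_BY_PHYLOGENY, 0) > 0
            and len(self.body_site_vocabulary) < 2
        ):
            raise ValueError("novel-by-phylogeny planting needs >= 2 body sites")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# sequence helpers


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def mutate(seq: str, n_subs: int, rng: np.random.Generator, margin: int = TERMINAL_MARGIN) -> str:
    """Substitute ``n_subs`` interior positions, each to a different base."""
    interior = len(seq) - 2 * margin
    if n_subs > interior:
        raise ValueError("more substitutions than mutable positions")
    positions = rng.choice(interior, size=n_subs, replace=False) + margin
    out = list(seq)
    for pos in positions:
        current = out[pos]
        choices = [b for b in "ACGT" if b != current]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# reference collection


@dataclass
class ReferenceCollection:
    entries: list[ReferenceEntry]
    genome_seqs: dict[str, str]  # genome_id -> full genome sequence
    genome_source: dict[str, str]  # genome_id -> public | novel
    genome_phylum: dict[str, str]


def simulate_reference_collection(
    config: SimulationConfig, rng: np.random.Generator
) -> ReferenceCollection:
    """Reference 16S set: mutually divergent genes, a subset with genomes.

    All pairwise 16S divergences are >= 3% by construction (verified by
    Hamming distance, exact under the substitution-only model; violating
    genes are resampled), so clustering at 99% identity keeps every
    reference in its own cluster. A ``sequenced_fraction`` subset carries a
    genome, taxonomy, body site, and a public/novel database split.
    """
    L = config.gene_16s_length_bp
    ancestor = _random_dna(rng, L)
    min_pairwise = int(0.04 * L)  # 4% floor, safely past the 3% requirement
    genes: list[str] = []
    while len(genes) < config.n_reference_genomes:
        k = int(rng.integers(int(0.08 * L), int(0.13 * L)))
        gene = mutate(ancestor, k, rng)
        if all(hamming(gene, g) >= min_pairwise for g in genes):
            genes.append(gene)

    n_sequenced = max(1, round(config.sequenced_fraction * config.n_reference_genomes))
    n_novel = max(1, round(config.novel_genome_fraction * n_sequenced))
    sites = config.body_site_vocabulary
    entries: list[ReferenceEntry] = []
    genome_seqs: dict[str, str] = {}
    genome_source: dict[str, str] = {}
    genome_phylum: dict[str, str] = {}
    for i, gene in enumerate(genes):
        ref_id = f"REF{i + 1:03d}"
        phylum = PHYLA[i % len(PHYLA)]
        taxonomy = ("Bacteria", phylum, f"Genus{i + 1}", f"species{i + 1}")
        if i < n_sequenced:
            genome_id = f"G{i + 1:03d}"
            site = sites[int(rng.integers(0, len(sites)))]
            flank_total = config.genome_length_bp - L
            left = int(rng.integers(0, flank_total + 1))
            genome = _random_dna(rng, left) + gene + _random_dna(rng, flank_total - left)
            genome_seqs[genome_id] = genome
            # the last n_novel sequenced genomes are the "new" contributions
            genome_source[genome_id] = "novel" if i >= n_sequenced - n_novel else "public"
            genome_phylum[genome_id] = phylum
            entries.append(
                ReferenceEntry(
                    ref_id=ref_id,
                    sequence=gene,
                    genome_id=genome_id,
                    taxonomy=taxonomy,
                    body_site_broad=site,
                    source_db="SEQUENCED_GENOME",
                )
            )
        else:
            entries.append(
                ReferenceEntry(ref_id=ref_id, sequence=gene, taxonomy=taxonomy)
            )
    return ReferenceCollection(entries, genome_seqs, genome_source, genome_phylum)


# ---------------------------------------------------------------------------
# query collection


def _category_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n samples across categories."""
    order = sorted(fractions)
    floors = {c: int(np.floor(fractions[c] * n)) for c in order}
    remainder = n - sum(floors.values())
    by_frac = sorted(order, key=lambda c: (-(fractions[c] * n - floors[c]), c))
    for c in by_frac[:remainder]:
        floors[c] += 1
    return floors


def _detailed_for(broad: str, rng: np.random.Generator) -> str:
    options = DETAILED_SITES.get(broad, [broad.lower()])
    return options[int(rng.integers(0, len(options)))]


def simulate_query_collection(
    config: SimulationConfig,
    references: ReferenceCollection,
    rng: np.random.Generator,
) -> tuple[list[SeqRecord16S], dict]:
    """Query collection with planted categories and a per-sample truth set.

    Truth per sample: planted category, source reference(s), body site,
    Hamming distance of the representative replicate to its source gene,
    and the expected priority tier from the straight-line tier oracle.
    """
    sequenced = [e for e in references.entries if e.source_db == "SEQUENCED_GENOME"]
    unsequenced = [e for e in references.entries if e.source_db != "SEQUENCED_GENOME"]
    if not sequenced:
        raise ValueError("query simulation needs at least one sequenced reference")
    counts = _category_counts(config.planted_fractions, config.n_query_samples)
    if counts.get(CONTAMINATED, 0) > 0:
        if config.replicates_per_sample < 2:
            raise ValueError("contamination planting needs >= 2 replicates per sample")
        if len(references.entries) < 2:
            raise ValueError("contamination planting needs >= 2 references")

    records: list[SeqRecord16S] = []
    truth_samples: dict[str, dict] = {}
    sample_no = 0
    nbp_toggle = 0

    def _next_id() -> str:
        nonlocal sample_no
        sample_no += 1
        return f"S{sample_no:04d}"

    def _replicates(sample_id: str, parents: Sequence[str], detailed: str, broad: str) -> None:
        for j in range(config.replicates_per_sample):
            parent = parents[j % len(parents)]
            noise = int(rng.integers(0, 3)) if config.replicate_noise_rate > 0 else 0
            records.append(
                SeqRecord16S(
                    sample_id=sample_id,
                    replicate_id=f"r{j + 1}",
                    sequence=mutate(parent, noise, rng),
                    body_site_detailed=detailed,
                    body_site_broad=broad,
                    source_note="synthetic isolate",
                )
            )

    for _ in range(counts.get(KNOWN, 0)):
        sid = _next_id()
        ref = sequenced[int(rng.integers(0, len(sequenced)))]
        k = int(rng.integers(SUB_RANGES[KNOWN][0], SUB_RANGES[KNOWN][1] + 1))
        parent = mutate(ref.sequence, k, rng)
        broad = ref.body_site_broad
        _replicates(sid, [parent], _detailed_for(broad, rng), broad)
        truth_samples[sid] = {"category": KNOWN, "source_refs": [ref.ref_id], "body_site_broad": broad}

    for _ in range(counts.get(NOVEL_BY_PHYLOGENY, 0)):
        sid = _next_id()
        use_unsequenced = bool(unsequenced) and nbp_toggle % 2 == 0
        nbp_toggle += 1
        k = int(rng.integers(SUB_RANGES[NOVEL_BY_PHYLOGENY][0], SUB_RANGES[NOVEL_BY_PHYLOGENY][1] + 1))
        if use_unsequenced:
            ref = unsequenced[int(rng.integers(0, len(unsequenced)))]
            broad = config.body_site_vocabulary[int(rng.integers(0, len(config.body_site_vocabulary)))]
        else:
            ref = sequenced[int(rng.integers(0, len(sequenced)))]
            others = [s for s in config.body_site_vocabulary if s != ref.body_site_broad]
            broad = others[int(rng.integers(0, len(others)))]
        parent = mutate(ref.sequence, k, rng)
        _replicates(sid, [parent], _detailed_for(broad, rng), broad)
        truth_samples[sid] = {
            "category": NOVEL_BY_PHYLOGENY,
            "source_refs": [ref.ref_id],
            "body_site_broad": broad,
        }

    for _ in range(counts.get(NOVEL, 0)):
        sid = _next_id()
        ref = references.entries[int(rng.integers(0, len(references.entries)))]
        k = int(rng.integers(SUB_RANGES[NOVEL][0], SUB_RANGES[NOVEL][1] + 1))
        parent = mutate(ref.sequence, k, rng)
        broad = config.body_site_vocabulary[int(rng.integers(0, len(config.body_site_vocabulary)))]
        _replicates(sid, [parent], _detailed_for(broad, rng), broad)
        truth_samples[sid] = {"category": NOVEL, "source_refs": [ref.ref_id], "body_site_broad": broad}

    for _ in range(counts.get(CONTAMINATED, 0)):
        sid = _next_id()
        i, j = rng.choice(len(references.entries), size=2, replace=False)
        ref_a, ref_b = references.entries[int(i)], references.entries[int(j)]
        ka = int(rng.integers(SUB_RANGES[CONTAMINATED][0], SUB_RANGES[CONTAMINATED][1] + 1))
        kb = int(rng.integers(SUB_RANGES[CONTAMINATED][0], SUB_RANGES[CONTAMINATED][1] + 1))
        parents = [mutate(ref_a.sequence, ka, rng), mutate(ref_b.sequence, kb, rng)]
        broad = ref_a.body_site_broad or config.body_site_vocabulary[0]
        _replicates(sid, parents, _detailed_for(broad, rng), broad)
        truth_samples[sid] = {
            "category": CONTAMINATED,
            "source_refs": [ref_a.ref_id, ref_b.ref_id],
            "body_site_broad": broad,
        }

    # representative replicate = longest, tie lexicographic id; lengths are
    # equal under the substitution-only model, so r1. Record its distance
    # to the source gene (replicate noise may revert parent substitutions).
    ref_seq_by_id = {e.ref_id: e.sequence for e in references.entries}
    rep_by_sample = {}
    for rec in records:
        cur = rep_by_sample.get(rec.sample_id)
        if cur is None or (-rec.length, rec.replicate_id) < (-cur.length, cur.replicate_id):
            rep_by_sample[rec.sample_id] = rec
    for sid, info in truth_samples.items():
        rep = rep_by_sample[sid]
        info["representative_replicate"] = rep.replicate_id
        info["k_rep"] = hamming(rep.sequence, ref_seq_by_id[info["source_refs"][0]])

    tiers = expected_tiers(truth_samples)
    for sid, tier in tiers.items():
        truth_samples[sid]["expected_tier"] = tier
    return records, {"samples": truth_samples}


# ---------------------------------------------------------------------------
# independent tier oracle


def expected_tiers(
    truth_samples: Mapping[str, dict],
    per_cluster_cap_tier4: int = 5,
    desirable_sites: Sequence[str] = ("Blood", "Peritoneal fluid", "Wound", "Joint", "Bone"),
) -> dict[str, int | None]:
    """Straight-line transcription of the six tier rules over truth labels.

    Works purely from planted categories, source references, body sites,
    and substitution counts — it never calls the prioritization module.
    Contaminated samples (removed by QC upstream) get no tier.
    """
    live = {s: t for s, t in truth_samples.items() if t["category"] != CONTAMINATED}

    def cluster_of(sid: str) -> str:
        # novel samples fall below the clustering threshold -> singleton
        if live[sid]["category"] == NOVEL:
            return f"singleton.{sid}"
        return live[sid]["source_refs"][0]

    clusters: dict[str, list[str]] = {}
    for sid in live:
        clusters.setdefault(cluster_of(sid), []).append(sid)

    # within-cluster rank: most divergent first (identity ascending), ties
    # on sample id; all sequences share one length
    rank: dict[str, int] = {}
    for members in clusters.values():
        ordered = sorted(members, key=lambda s: (-live[s]["k_rep"], s))
        for i, sid in enumerate(ordered):
            rank[sid] = i + 1

    tier: dict[str, int | None] = {s: None for s in truth_samples}

    for sid in live:
        if live[sid]["category"] == NOVEL:
            tier[sid] = 1

    for members in clusters.values():
        nbp = [s for s in members if live[s]["category"] == NOVEL_BY_PHYLOGENY]
        if nbp:
            top = min(nbp, key=lambda s: rank[s])
            tier[top] = 2

    for members in clusters.values():
        if all(live[s]["category"] == KNOWN for s in members):
            top = min(members, key=lambda s: rank[s])
            tier[top] = 3

    for members in clusters.values():
        site_counts = Counter(live[s]["body_site_broad"] for s in members)
        candidates = [
            s
            for s in members
            if live[s]["category"] == NOVEL_BY_PHYLOGENY
            and tier[s] is None
            and site_counts[live[s]["body_site_broad"]] == 1
        ]
        for s in sorted(candidates, key=lambda s: rank[s])[:per_cluster_cap_tier4]:
            tier[s] = 4

    for sid in live:
        if live[sid]["category"] == NOVEL_BY_PHYLOGENY and tier[sid] is None:
            tier[sid] = 5

    for members in clusters.values():
        site_counts = Counter(live[s]["body_site_broad"] for s in members)
        for s in members:
            if (
                live[s]["category"] == KNOWN
                and tier[s] is None
                and site_counts[live[s]["body_site_broad"]] == 1
            ):
                tier[s] = 6

    return tier


# ---------------------------------------------------------------------------
# shotgun reads with truth alignments


def simulate_reads(
    config: SimulationConfig,
    references: ReferenceCollection,
    rng: np.random.Generator,
    outdir: str | Path,
) -> dict:
    """Shotgun read sets plus truth SAMs against baseline/augmented databases.

    Per read sample: reads drawn uniformly within genomes, weighted across
    genomes by a Dirichlet abundance vector; substitution errors at
    ``read_error_rate``; a fraction of reads carries planted quality-2
    tails (trimmable) and a smaller fraction is junk (post-trim length
    below the cleaning floor). Truth alignments place each surviving read
    at its true origin: the baseline SAM covers only public genomes, the
    augmented SAM additionally the novel genomes, so augmented ⊇ baseline
    by construction. An extra genome in neither database absorbs
    ``unknown_genome_weight`` of reads (the unmappable fraction).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_ids = sorted(references.genome_seqs)
    if not genome_ids:
        raise ValueError("no genomes to simulate reads from")
    unknown_id = "G_UNKNOWN"
    unknown_seq = _random_dna(rng, config.genome_length_bp)
    seqs = dict(references.genome_seqs)
    seqs[unknown_id] = unknown_seq

    public = [g for g in genome_ids if references.genome_source[g] == "public"]
    novel = [g for g in genome_ids if references.genome_source[g] == "novel"]
    baseline_sq = [{"SN": g, "LN": len(seqs[g])} for g in public]
    augmented_sq = [{"SN": g, "LN": len(seqs[g])} for g in public + novel]
    L = config.read_length
    sites = config.body_site_vocabulary

    samples = {}
    for s in range(config.n_read_samples):
        sample_id = f"HMP{s + 1:03d}"
        body_site = sites[s % len(sites)]
        weights = rng.dirichlet(np.full(len(genome_ids), 0.5))
        weights = np.concatenate(
            [(1 - config.unknown_genome_weight) * weights, [config.unknown_genome_weight]]
        )
        pool = genome_ids + [unknown_id]
        reads = []
        for r in range(config.n_reads_per_sample):
            gid = pool[int(rng.choice(len(pool), p=weights))]
            gseq = seqs[gid]
            pos = int(rng.integers(0, len(gseq) - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            n_err = int(rng.binomial(L, config.read_error_rate))
            slice_err = mutate(gseq[pos : pos + L], n_err, rng, margin=0) if n_err else gseq[pos : pos + L]
            fastq_seq = slice_err if strand == "+" else _revcomp(slice_err)
            quals = rng.integers(30, 41, size=L).tolist()
            s_trim = e_trim = 0
            u = rng.random()
            if u < config.junk_read_fraction:
                e_trim = L - 50  # leaves 50 bp, below the 60 bp cleaning floor
            elif u < config.junk_read_fraction + config.lowq_tail_fraction:
                s_trim = int(rng.integers(0, 8))
                e_trim = int(rng.integers(3, 20))
            for i in range(s_trim):
                quals[i] = 2
            for i in range(L - e_trim, L):
                quals[i] = 2
            survives = L - s_trim - e_trim >= 60
            reads.append(
                {
                    "read_id": f"{sample_id}.read{r + 1}",
                    "genome": gid,
                    "pos": pos,
                    "strand": strand,
                    "seq": fastq_seq,
                    "slice_err": slice_err,
                    "quals": quals,
                    "s_trim": s_trim,
                    "e_trim": e_trim,
                    "survives": survives,
                }
            )

        fastq_path = outdir / f"{sample_id}.fastq"
        with open(fastq_path, "w") as fh:
            for rd in reads:
                qstr = "".join(chr(q + 33) for q in rd["quals"])
                fh.write(f"@{rd['read_id']}\n{rd['seq']}\n+\n{qstr}\n")

        def _write_sam(path: Path, sq: list[dict], allowed: set[str]) -> None:
            header = {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": sq}
            tid = {d["SN"]: i for i, d in enumerate(sq)}
            with pysam.AlignmentFile(str(path), "w", header=header) as sam:
                for rd in reads:
                    if not rd["survives"] or rd["genome"] not in allowed:
                        continue
                    s_t, e_t = rd["s_trim"], rd["e_trim"]
                    clean_len = L - s_t - e_t
                    a = pysam.AlignedSegment(sam.header)
                    a.query_name = rd["read_id"]
                    a.flag = 0 if rd["strand"] == "+" else 16
                    a.reference_id = tid[rd["genome"]]
                    # a start-trim on a reverse-strand read removes the
                    # reference-3' end, so the mapped start shifts by the
                    # end trim instead
                    a.reference_start = rd["pos"] + (s_t if rd["strand"] == "+" else e_t)
                    a.mapping_quality = 60
                    a.cigarstring = f"{clean_len}M"
                    if rd["strand"] == "+":
                        a.query_sequence = rd["slice_err"][s_t : L - e_t]
                        a.query_qualities = pysam.qualitystring_to_array(
                            "".join(chr(q + 33) for q in rd["quals"][s_t : L - e_t])
                        )
                    else:
                        a.query_sequence = rd["slice_err"][e_t : L - s_t]
                        a.query_qualities = pysam.qualitystring_to_array(
                            "".join(chr(q + 33) for q in rd["quals"][s_t : L - e_t][::-1])
                        )
                    sam.write(a)

        baseline_path = outdir / f"{sample_id}.baseline.sam"
        augmented_path = outdir / f"{sample_id}.augmented.sam"
        _write_sam(baseline_path, baseline_sq, set(public))
        _write_sam(augmented_path, augmented_sq, set(public + novel))

        survivors = [rd for rd in reads if rd["survives"]]
        samples[sample_id] = {
            "body_site": body_site,
            "fastq": fastq_path.name,
            "baseline_sam": baseline_path.name,
            "augmented_sam": augmented_path.name,
            "n_reads": len(reads),
            "n_cleaned": len(survivors),
            "n_from_public": sum(rd["genome"] in set(public) for rd in survivors),
            "n_from_novel": sum(rd["genome"] in set(novel) for rd in survivors),
            "n_from_unknown": sum(rd["genome"] == unknown_id for rd in survivors),
            "reads": [
                {
                    "read_id": rd["read_id"],
                    "genome": rd["genome"],
                    "pos": rd["pos"],
                    "strand": rd["strand"],
                    "survives": rd["survives"],
                }
                for rd in reads
            ],
        }
    with open(outdir / "read_samples.tsv", "w") as fh:
        fh.write("sample_id\tbody_site\tfastq\tbaseline_sam\taugmented_sam\n")
        for sample_id in sorted(samples):
            info = samples[sample_id]
            fh.write(
                f"{sample_id}\t{info['body_site']}\t{info['fastq']}\t"
                f"{info['baseline_sam']}\t{info['augmented_sam']}\n"
            )
    return {
        "public_genomes": public,
        "novel_genomes": novel,
        "unknown_genome": unknown_id,
        "samples": samples,
    }


# ---------------------------------------------------------------------------
# top-level emitter


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write every pipeline input under ``outdir``; return the truth set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    refs = simulate_reference_collection(config, rng)
    write_reference_fasta(refs.entries, outdir / "references.fasta", outdir / "references.tsv")
    with open(outdir / "genome_metadata.tsv", "w") as fh:
        fh.write("genome_id\tphylum\tsource\n")
        for gid in sorted(refs.genome_seqs):
            fh.write(f"{gid}\t{refs.genome_phylum[gid]}\t{refs.genome_source[gid]}\n")

    records, truth = simulate_query_collection(config, refs, rng)
    write_fasta_with_metadata(records, outdir / "queries.fasta", outdir / "queries.tsv")

    reads_truth = simulate_reads(config, refs, rng, outdir / "reads")
    truth["reads"] = reads_truth
    config.to_yaml(outdir / "sim_config.yaml")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
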