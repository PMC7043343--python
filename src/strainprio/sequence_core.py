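"""Sequence containers, FASTA/TSV I/O, and the pairwise identity/coverage metric.

Every downstream stage (clustering, novelty screening, QC) scores sequence
pairs with the same local-alignment metric defined here: BLASTN-like
percent identity over alignment columns (gap columns included in the
denominator) and coverage of the *query* span.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

METADATA_COLUMNS = [
    "sample_id",
    "replicate_id",
    "body_site_detailed",
    "body_site_broad",
    "source_note",
]

HITS_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "qcovs",
    "length",
    "qstart",
    "qend",
    "sstart",
    "send",
    "score",
]


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


class DuplicateRecordError(ValueError):
    """Raised when two records share the same (sample_id, replicate_id)."""


@dataclass
class SeqRecord16S:
    """One full-length 16S replicate sequence with its isolate metadata."""

    sample_id: str
    replicate_id: str
    sequence: str
    body_site_detailed: str = ""
    body_site_broad: str = "Unknown"
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.sample_id}.{self.replicate_id}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise SequenceAlphabetError(
                f"{self.sample_id}.{self.replicate_id}: illegal characters {sorted(bad)}"
            )
        if not self.body_site_broad:
            self.body_site_broad = "Unknown"

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def record_id(self) -> str:
        return f"{self.sample_id}.{self.replicate_id}"


@dataclass
class ReferenceEntry:
    """A known 16S sequence, optionally tied to a sequenced genome.

    ``source_db`` distinguishes 16S-only database entries (SILVA/RDP-like)
    from 16S genes extracted from fully sequenced genomes; only the latter
    carry a ``genome_id`` and an isolation body site.
    """

    ref_id: str
    sequence: str
    genome_id: str | None = None
    taxonomy: tuple[str, ...] = ()
    body_site_broad: str | None = None
    source_db: str = "SILVA_RDP_LIKE"  # or "SEQUENCED_GENOME"

    def __post_init__(self) -> None:
        if self.source_db == "SEQUENCED_GENOME" and self.genome_id is None:
            raise ValueError(f"{self.ref_id}: sequenced-genome entry without genome_id")


@dataclass(frozen=True)
class AlignmentHit:
    """Pairwise local-alignment result (BLAST outfmt-6-like semantics).

    Coordinates are 1-based inclusive. ``pct_identity`` uses alignment
    columns (including gap columns) as denominator; ``query_coverage`` is
    the aligned query span over the full query length.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    query_coverage: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float


@dataclass
class AlignmentScoring:
    """BLASTN-like local alignment scoring.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST
    convention). ``min_score`` is the floor below which best_hit treats an
    alignment as no hit. ``coverage_side`` records that coverage is
    measured on the query; it is configurable but only "query" is
    implemented.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    min_score: float = 20.0
    coverage_side: str = "query"

    def build_aligner(self) -> Align.PairwiseAligner:
        matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
        for a in "ACGTN":
            for b in "ACGTN":
                # N never matches, not even itself
                matrix[a, b] = self.match if (a == b and a != "N") else self.mismatch
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = matrix
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCORING = AlignmentScoring()

_aligner_cache: dict[tuple, Align.PairwiseAligner] = {}


def _get_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    key = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    if key not in _aligner_cache:
        _aligner_cache[key] = scoring.build_aligner()
    return _aligner_cache[key]


def _validate_dna(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceAlphabetError(f"{label}: illegal characters {sorted(bad)}")


def align_pair(
    query: str,
    subject: str,
    query_id: str = "query",
    subject_id: str = "subject",
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> AlignmentHit | None:
    """Local-align ``query`` against ``subject`` and report identity/coverage.

    Returns ``None`` in the degenerate case where no positive-scoring local
    alignment exists (completely dissimilar short sequences).
    """
    _validate_dna(query, query_id)
    _validate_dna(subject, subject_id)
    aligner = _get_aligner(scoring)
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return None
    best = alignments[0]
    q_blocks, s_blocks = best.aligned
    if len(q_blocks) == 0:
        return None
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    s_start, s_end = int(s_blocks[0][0]), int(s_blocks[-1][1])
    paired = 0
    matches = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        paired += qe - qs
        for cq, cs in zip(query[qs:qe], subject[ss:se]):
            if cq == cs and cq != "N":
                matches += 1
    q_span = q_end - q_start
    s_span = s_end - s_start
    aln_length = q_span + s_span - paired  # paired columns + gap columns
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        pct_identity=100.0 * matches / aln_length,
        query_coverage=100.0 * q_span / len(query),
        aln_length=aln_length,
        q_start=q_start + 1,
        q_end=q_end,
        s_start=s_start + 1,
        s_end=s_end,
        score=float(best.score),
    )


def select_best(
    hits: Iterable[AlignmentHit | None], min_score: float = DEFAULT_SCORING.min_score
) -> AlignmentHit | None:
    """Pick the hit maximizing (identity, coverage, score), ties on subject id."""
    best: AlignmentHit | None = None
    best_key: tuple[float, float, float] | None = None
    for hit in hits:
        if hit is None or hit.score < min_score:
            continue
        key = (hit.pct_identity, hit.query_coverage, hit.score)
        if (
            best_key is None
            or key > best_key
            or (key == best_key and hit.subject_id < best.subject_id)
        ):
            best, best_key = hit, key
    return best


def best_hit(
    query: SeqRecord16S | tuple[str, str],
    refs: Iterable[ReferenceEntry],
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> AlignmentHit | None:
    """Best reference hit for a query, maximizing (identity, coverage, score).

    Ties break on lexicographic subject id. Hits scoring below
    ``scoring.min_score`` are discarded; returns ``None`` when no reference
    yields a hit.
    """
    if isinstance(query, SeqRecord16S):
        qid, qseq = query.record_id, query.sequence
    else:
        qid, qseq = query
    hits = (
        align_pair(qseq, ref.sequence, qid, ref.ref_id, scoring)
        for ref in sorted(refs, key=lambda r: r.ref_id)
    )
    return select_best(hits, scoring.min_score)


# ---------------------------------------------------------------------------
# I/O


def read_fasta_with_metadata(
    fasta_path: str | Path, metadata_tsv_path: str | Path
) -> list[SeqRecord16S]:
    """Read query 16S FASTA plus its per-sample metadata sidecar.

    FASTA IDs are ``sampleID.replicateID``; the TSV has one row per
    sample_id. FASTA records with no metadata row are dropped with a
    warning; duplicate (sample_id, replicate_id) pairs are a hard error.
    """
    meta: dict[str, dict[str, str]] = {}
    with open(metadata_tsv_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["sample_id"]] = row
    records: list[SeqRecord16S] = []
    seen: set[tuple[str, str]] = set()
    used_samples: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sample_id, _, replicate_id = rec.id.partition(".")
        if not replicate_id:
            replicate_id = "r1"
        key = (sample_id, replicate_id)
        if key in seen:
            raise DuplicateRecordError(f"duplicate record {sample_id}.{replicate_id}")
        seen.add(key)
        row = meta.get(sample_id)
        if row is None:
            warnings.warn(f"no metadata for FASTA record {rec.id}; dropped")
            continue
        used_samples.add(sample_id)
        records.append(
            SeqRecord16S(
                sample_id=sample_id,
                replicate_id=replicate_id,
                sequence=str(rec.seq).upper(),
                body_site_detailed=row.get("body_site_detailed", ""),
                body_site_broad=row.get("body_site_broad", "") or "Unknown",
                source_note=row.get("source_note", ""),
            )
        )
    for sample_id in sorted(set(meta) - used_samples):
        warnings.warn(f"metadata row {sample_id} has no sequence; dropped")
    return records


def write_fasta_with_metadata(
    records: Sequence[SeqRecord16S], fasta_path: str | Path, metadata_tsv_path: str | Path
) -> None:
    """Inverse of :func:`read_fasta_with_metadata` (one metadata row per sample)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.record_id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    with open(metadata_tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        done: set[str] = set()
        for r in records:
            if r.sample_id in done:
                continue
            done.add(r.sample_id)
            writer.writerow(
                [r.sample_id, r.replicate_id, r.body_site_detailed, r.body_site_broad, r.source_note]
            )


def read_reference_fasta(
    fasta_path: str | Path, metadata_tsv_path: str | Path
) -> list[ReferenceEntry]:
    """Read a reference 16S FASTA with taxonomy/genome metadata sidecar."""
    meta: dict[str, dict[str, str]] = {}
    with open(metadata_tsv_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            meta[row["ref_id"]] = row
    entries = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        row = meta.get(rec.id, {})
        genome_id = row.get("genome_id") or None
        entries.append(
            ReferenceEntry(
                ref_id=rec.id,
                sequence=str(rec.seq).upper(),
                genome_id=genome_id,
                taxonomy=tuple(row.get("taxonomy", "").split(";")) if row.get("taxonomy") else (),
                body_site_broad=row.get("body_site_broad") or None,
                source_db=row.get("source_db", "SILVA_RDP_LIKE"),
            )
        )
    return entries


def write_reference_fasta(
    entries: Sequence[ReferenceEntry], fasta_path: str | Path, metadata_tsv_path: str | Path
) -> None:
    seq_records = [SeqRecord(Seq(e.sequence), id=e.ref_id, description="") for e in entries]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    with open(metadata_tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["ref_id", "genome_id", "taxonomy", "body_site_broad", "source_db"])
        for e in entries:
            writer.writerow(
                [e.ref_id, e.genome_id or "", ";".join(e.taxonomy), e.body_site_broad or "", e.source_db]
            )


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in BLAST outfmt-6-like TSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(HITS_COLUMNS)
        for h in hits:
            writer.writerow(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.pct_identity:.3f}",
                    f"{h.query_coverage:.3f}",
                    h.aln_length,
                    h.q_start,
                    h.q_end,
                    h.s_start,
                    h.s_end,
                    f"{h.score:g}",
                ]
            )
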