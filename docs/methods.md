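# Methods

## Problem and scope

Clinical culture collections can hold thousands of bacterial isolates of
which only a fraction is worth whole-genome sequencing: strains already
represented in public genome databases add little, while strains from
divergent lineages or under-sampled body habitats add a lot. `strainprio`
implements the computational side of a targeted prioritization workflow
driven by full-length 16S rRNA gene sequences:

1. score every isolate's 16S against a reference database (pairwise local
   alignment, percent identity and query coverage);
2. cluster the reference database and assign isolates to representatives;
3. remove contaminated isolates (replicate cluster conflicts, assembly
   genus conflicts) and harmonize body-site metadata;
4. call each isolate **novel**, **novel by phylogeny**, or **known**, and
   rank everything into six sequencing-priority tiers;
5. quantify what the newly sequenced genomes add to a baseline genome
   database, by re-counting metagenomic read mapping against both.

Wet-lab steps and external tools that surround this workflow in practice
(amplicon sequencing, genome assembly and annotation, BUSCO, read mapping
itself, human-read masking, duplicate removal) are out of scope: their
outputs (16S FASTA, SAM alignments, FASTQ reads, contig top-hit tables)
are inputs here.

## Alignment metric

All sequence comparisons use one local alignment metric
(`sequence_core.align_pair`), computed with Biopython's
`PairwiseAligner` under BLASTN-like scores: match +2, mismatch −3, and a
gap of length *k* costing 5 + 2*k*. A custom ACGTN substitution matrix
makes `N` match nothing, including itself — conservative toward novelty.

* **Percent identity** is matches over alignment columns, *including gap
  columns* in the denominator (BLAST convention).
* **Coverage** is the aligned span of the *query* over the query length.
  The direction is deliberate and configurable
  (`AlignmentScoring.coverage_side`); identity is symmetric for fully
  aligned pairs, coverage is not.
* Coordinates are 1-based inclusive; hits are exported as BLAST
  outfmt-6-like TSV.
* Alignments scoring below `min_score` (default 20, i.e. ten matching
  bases) are treated as "no hit".

Co-optimal local alignments exist; the aligner's first traceback is used.
The test suite checks score, identity and coverage against a full
unbanded affine-gap dynamic program that enumerates all optimal
tracebacks.

## Clustering

`clustering.greedy_cluster` is CD-HIT-style greedy clustering: sequences
are visited longest-first (ties broken on ID), and each joins the
*best-matching* existing representative that passes **both** the identity
and the coverage threshold (defaults 99% identity over 95% coverage,
inclusive), else founds a new cluster. Joining the best match rather than
the first passing one makes the partition independent of encounter order;
canonical ordering makes it independent of input order. The
representative is the longest member by construction. Query isolates are
then assigned to these fixed representatives under the same rule
(`assign_to_representatives`); queries matching no representative are
`UNCLUSTERED`.

Borderline members near the 99.0% boundary are sensitive to the exact
greedy path; the synthetic generator therefore plants members far from
the boundary and tests compare against an all-pairs brute-force oracle.

## Contamination QC

* **Replicate conflict**: a sample whose technical replicates land in ≥ 2
  distinct cluster labels is contaminated. Replicates that are
  `UNCLUSTERED` get pseudo-labels by single-linkage grouping *among
  themselves* at the clustering thresholds, so two concordant replicates
  of a genuinely novel strain (both unclustered) are **not** a conflict —
  avoiding false positives on exactly the strains the screen exists to
  find. Single-replicate samples can never be flagged. Clean samples keep
  one representative replicate: longest, ties on replicate ID.
* **Genus conflict**: a strain whose assembly supercontigs have top hits
  in ≥ 2 distinct genera is contaminated; contigs with no hit are
  ignored. This rule consumes an externally produced contig→genus table.
* **Body-site collapsing** maps free-text isolation sources to broad
  habitat categories via a shipped, editable TSV of case-insensitive
  substring patterns (longest pattern wins, start-anchored matches take
  precedence); unmatched sites become `Unknown`.

## Novelty calls

With inclusive thresholds (defaults 97% identity, 90% coverage):

* **NOVEL** — best database hit has identity ≤ 97% *or* coverage ≤ 90%,
  or there is no hit;
* **NOVEL_BY_PHYLOGENY** — not novel by similarity, but the sample's
  cluster contains no sequenced-genome 16S, or every sequenced co-member
  was isolated from a different broad body site (unclustered samples
  qualify trivially);
* **KNOWN** — everything else.

NOVEL takes precedence over NOVEL_BY_PHYLOGENY. Lowering the identity
cutoff can only shrink the NOVEL set (tested property).

## Priority tiers

Within each cluster, members are ranked novelty-first: ascending best-hit
identity with no-hit samples first, ties broken by descending length then
sample ID. The six tiers:

1. all NOVEL samples;
2. the top-ranked NOVEL_BY_PHYLOGENY member of each cluster containing
   one;
3. the top member of each all-KNOWN cluster;
4. non-top NOVEL_BY_PHYLOGENY members whose broad body site occurs
   exactly once in their cluster, at most `per_cluster_cap_tier4`
   (default 5) per cluster, in rank order;
5. remaining NOVEL_BY_PHYLOGENY members, ordered by within-cluster rank,
   then membership in the configurable `desirable_sites` list (default
   Blood, Peritoneal fluid, Wound, Joint, Bone, in that order), then
   ascending site frequency among the tier's candidates;
6. KNOWN samples whose body site is unique within their cluster.

Samples fitting no tier remain unassigned. The final list takes tiers in
order, skipping samples flagged unavailable (an input list — availability
is a wet-lab property) without consuming slots. Design choices that the
workflow leaves open — the within-cluster ranking key, "unique isolation
source" scoped to the cluster, and the desirable-then-rare ordering of
tier 5 — are exposed in `RankingConfig` and documented as defaults, not
facts about any particular study.

## Mapping evaluation

* **Read cleaning**: trim maximal runs of quality ≤ 2 from both read
  ends, then drop reads whose longest run of consecutive non-N bases is
  under 60.
* **Sample outliers**: per body site, drop samples with cleaned-read
  counts strictly above mean + 3 SD (population SD, computed once,
  non-iterative), then the ⌊0.05·n⌋ smallest samples per site. Note that
  with a single extreme value among n ≤ 10 samples the maximum z-score
  cannot exceed 3, so the SD rule only bites with enough samples per
  site.
* **Coverage**: per genome, breadth is the fraction of positions under
  the union of reference intervals covered by aligned read bases
  (CIGAR M/=/X; deletions consume reference but do not cover it, the
  samtools convention), and depth is mean per-base coverage (total
  aligned bases over genome length). Only primary mapped alignments
  count, for both coverage and read counting; genome lengths come from
  the SAM `@SQ` header. **High representation** means breadth ≥ 0.5 and
  mean depth ≥ 1.0, inclusive.
* **Improvement tables**: per body site / phylum / sample, counts are
  summed and relative increase is 100·(augmented − baseline)/baseline; a
  zero baseline yields an undefined marker (NaN). A per-site report gives
  mean cleaned/mapped read counts per body site.
* **Enrichment**: one-sided Fisher's exact test (upper hypergeometric
  tail via `scipy.stats.hypergeom.sf`) for over-representation of
  high-representation genomes among the newly sequenced set versus the
  public set. Mean (not median) depth and the exact-test choice are
  deliberate defaults where the underlying procedure is underspecified.

## Synthetic study

`synthetic.simulate_all` generates every input with truth labels, so the
whole pipeline is testable offline:

* a reference collection whose 16S genes are pairwise ≥ 4% divergent
  (so each reference is its own cluster at 99%); ~70% carry a sequenced
  genome with body site and taxonomy, and the sequenced genomes are split
  into a *public* (baseline) and a *novel* (augmentation) set;
* a query collection with planted categories — KNOWN (1–4 substitutions
  from a sequenced reference, same body site), NOVEL_BY_PHYLOGENY (6–9
  substitutions, from a 16S-only reference or with a swapped body site),
  NOVEL (75–105 substitutions), CONTAMINATED (replicates drawn from two
  different references) — with 2 technical replicates per sample carrying
  0–2 substitutions of replicate noise;
* shotgun read samples (default 6 samples × 1200 reads × 100 bp) with
  Dirichlet genome abundances, substitution errors, planted quality-2
  tails and junk reads, and truth SAMs written against the baseline and
  augmented databases (augmented ⊇ baseline by construction); a genome
  absent from both databases absorbs 10% of reads, emulating the
  unmappable fraction.

The mutation model is substitution-only and never touches a 20 bp margin
at either sequence end (mimicking conserved primer sites). Consequences:
planted alignments are full-length and gap-free, the realized identity of
a planted sample is exactly (L−k)/L, and truth labels follow from
substitution arithmetic. Planted substitution counts sit far from the
97%/99% decision boundaries (≈ 99.8%, ≈ 99.5%, ≈ 94% identity), so exact
label recovery is expected by construction — passing tests demonstrate
the machinery is consistent, *not* that real data with borderline
divergences, indels, chimeras or partial-length sequences would be
classified as cleanly. An indel-free generator also means query coverage
is always ~100%; the coverage arm of the novelty rule is exercised by
unit tests, not by the simulation.

`TruthSet.expected_tier` comes from `synthetic.expected_tiers`, a
deliberate straight-line re-transcription of the six tier rules operating
only on planted categories, source references, body sites and
substitution counts — it shares no code with `prioritization`, making the
end-to-end tier comparison a genuine dual-route check.

Everything is generated from one `numpy` `Generator` seeded by
`SimulationConfig.seed`; identical configurations produce byte-identical
FASTA/FASTQ/SAM/TSV/JSON artifacts.

## Problem sizes and determinism

The default synthetic study uses 10 reference genomes (20 kb each), 40
query samples × 2 replicates (1500 bp 16S), and 6 read samples of 1200
reads — sizes chosen so a complete pipeline run (≈ 1300 full-length
pairwise alignments) finishes in about a minute on one core while still
exercising every rule, including the tier-4 cap and multi-member
clusters. All stages are deterministic given the seed; rerunning a stage
with unchanged inputs reproduces identical bytes.

## Known limitations

* Tree-based novelty assessment (manual inspection of per-taxon
  phylogenies) is operationalized as the deterministic cluster rule;
  borderline outcomes can differ from a human call.
* The greedy cluster partition near threshold boundaries depends on the
  greedy order; only well-separated inputs have a unique answer.
* Coverage semantics (query-side), depth statistic (mean), the
  lower-outlier cutoff (per-site floor quantile) and the within-cluster
  ranking key are documented defaults for underspecified steps, each
  configurable.
* Multi-mapped reads are handled by trusting the mapper's primary
  alignment; no reassignment is attempted.
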