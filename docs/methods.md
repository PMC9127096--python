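# Methods

This note documents the models, parameter choices and numerical decisions
behind prolamin-scan, and what its synthetic validation does and does not
demonstrate about real data.

## The synthetic genome model

`synthetic_data.default_genome_model()` plants 34 elements on nine
chromosomes of a hexaploid-like genome (~188 kb total — loci plus
intergenic spacer, not a full genome):

* **Avenins** (17 genes + 3 fragments + 1 promoter) in three cassettes with
  the observed gene orders (chr1D `C1-B-C2-A`; chr3D `D, fragment, D` then
  `promoter-C1-B-C2-C2-A`; chrUn `fragment-D-C1-B-C2-C2-fragment-A`).
* **Globulins** (7 genes, groups A–D) on chr1A/1D/3D/7A/Un.
* **AATIs** (6 genes, families 1/2/3/unknown) on chr4A/4C/4D/7C/1D.

Counts are a deliberate desk-scale reduction of the study-scale landscape
(87 globulins, 23 AATIs); the avenin complement is kept at full size
because the epitope arithmetic depends on it.

**Avenin architecture.** Proteins are signal peptide (19 aa) + conserved1 +
repetitive1 + conserved2 + repetitive2 + conserved3 + C-terminal (fixed 15
aa). Conserved domains are fixed per-family exemplar blocks (diverged
deterministically between families over an alphabet excluding C/P/Q/L);
repetitive domains are tandem P/Q/L-rich hexa-to-heptapeptide repeats.
Cysteine placement: four in conserved2, four in conserved3, plus a ninth in
the group-A C-terminal domain. Each family carries its epitope once at the
start of repetitive1; C2 additionally carries the overlapping tandem block
`(PFVQQQQ)×r + PF`, r ∈ {2,3} (default 3), yielding exactly r overlapping
PFVQQQQPF matches. Protein lengths run 169–214 aa across families.

**Globulins** carry three introns (117/126/105 bp, within the observed
104–137 bp range). Intron lengths are multiples of three and their codons
are stop-free, so the unspliced genomic open reading frame stays intact;
this is what lets the pipeline call a globulin consensus "whole" without de
novo intron detection, which is out of scope. The literal shortest observed
intron (104 bp) is traded for 105 bp for this reason. Splice boundaries are
GT…AG.

**Gene starts are probe-compatible.** The first codons of each class encode
the family signal/leader peptide while matching the degenerate enrichment
probes (avenins `ATGARGAMCTTYCTCATC`, globulins `ATGGYAAYYAYYRGBWTBYSATC`,
AATIs `ATGGCGTCC`), so transcripts genuinely carry the probe motifs.

**Per-copy synonymous divergence.** Sibling copies of the same family would
otherwise be byte-identical and unmappable-to-locus. Each genomic copy gets
one synonymous codon swap per 23 codons (a distinct codon class per copy),
≈1 % nucleotide divergence — enough for unique read assignment, small
enough not to disturb classification. Exemplars are the swap-free base
sequences, so "exemplar ≠ any planted copy" holds by construction.

**What the generator does not emulate:** expression-level variation (reads
are uniform over transcripts — flagged in the config as an assumption),
homopolymer-biased long-read error profiles, chimeric reads, alternative
splicing, and genuinely unknown gene family members. Passing the round-trip
tests therefore shows the pipeline's logic is correct under i.i.d. noise
and known family structure; it does not certify performance on real SRA
data.

## Read simulation

Lengths ~ Normal(1027, 120) truncated to the transcript (floor 50 bp);
substitution/insertion/deletion applied i.i.d. per base (defaults 0; the
study conditions use 2 % substitution); ~50 % of reads reverse-complemented;
constant Phred-30 quality symbol, since nothing downstream uses qualities.

## Mapper

Canonical k-mer index (k = 15 odd in [11,21], repeat ceiling max_occ = 50),
anchors grouped per (chromosome, strand). Small anchor sets (≤ 80) are
chained by an exact O(n²) dynamic program (strictly increasing in read and
target, gaps ≤ max_gap = 500); larger sets are first clustered into
diagonal bands (offset drift ≤ 30) with a band-level DP — bands absorb
small indels, separate bands arise at introns or paralogous hits, and the
DP keeps a collinear subset. A read maps when the chain has ≥ 3 anchors
spanning ≥ 100 bp; identity is estimated as anchored bases / anchored read
span (no base-level alignment — the consensus stage re-anchors per locus).
Ties between equal chains resolve by (chromosome, position). Defaults
reflect that high-identity kilobase reads need only sparse anchoring.

## Loci and consensus

Mapped intervals merge when overlapping or book-ended (gap 0); loci with
< 3 supporting reads are dropped; the reduced reference takes each locus
± 50 bp flank, with records named `chrom-start`. Consensus is a
substitution-only majority pileup: reads are re-anchored by k-mers unique
in both read and locus reference, anchors are LIS-filtered, consecutive
same-offset anchors form runs, and only bases inside runs are placed — read
termini (adapter, poly-A) and bases stranded between conflicting-offset
runs (e.g. next to an intron junction disrupted by an error) are dropped
rather than guessed. Columns below min_depth = 3 emit the reference base;
ties resolve to the reference; alleles ≥ 20 % are recorded as variants.
This is a declared simplification of haplotype-aware variant calling:
insertions are skipped and deletions appear as missing coverage, which is
exact under the low-indel study conditions and keeps the stage fully
deterministic.

## Distances, trees, classification

`jc_distance` implements the Jukes–Cantor transform with gap/N columns
excluded and a saturation error at p ≥ 0.75. `pairwise_align` is global
Needleman–Wunsch (match +1, mismatch −1, linear gap −2; biopython's
PairwiseAligner, canonical first alignment for determinism).
Neighbor-joining is implemented directly (lowest-Q pair, ties by label
order, negative branch lengths clamped to 0) and is validated against
additive matrices and an independent implementation.

Family assignment does **not** use the plain gap-excluded distance: with a
linear gap penalty, the length difference between unrelated sequences is a
sunk cost whose placement is free, so the aligner scatters gaps to hide
mismatches and unrelated pairs can look deceptively close. The
classification metric instead uses a semi-global alignment (free end gaps,
affine penalties −4/−0.5) and counts *internal* gap columns as differences,
requires the aligned core to cover ≥ 80 % of one sequence, and treats
saturated pairs as infinitely distant. A gene whose best exemplar distance
exceeds max_dist = 1.0 is "unclassified" (this catches the promoter and
random sequence); truncated gene fragments still classify to their source
family through the free end gaps. ML tree search is out of scope: the
scientifically used output is the family assignment, and the dendrogram is
NJ on JC distances.

## Protein features

Status calling restricts the search to the read-covered span of the
consensus (internal coverage gaps ≤ 200 bp are bridged — introns — and
uncovered flanks are excluded, which keeps reference flank sequence from
contributing spurious ATGs or stops). The first ATG opens the frame; the
last in-frame stop ends the CDS; an earlier stop marks a pseudogene; no ATG
or CDS < 300 nt is a fragment.

Avenin segmentation: signal peptide fixed at residues 0–19; repetitive
domains are maximal runs with windowed (9-residue) P+Q+L content ≥ 0.55,
run length ≥ 15, with 1–3 residue dips bridged (epitope heads are slightly
less P/Q/L-rich than the repeats that follow); the C-terminal domain is the
final 15 residues, matching the generator's fixed-length tail — a
convention, since composition alone cannot locate that boundary. Exactly
two repetitive runs are required, otherwise a segmentation-failure flag is
raised. Recovered boundaries agree with planted truth within ±3 residues.

Composition tables include the signal peptide by default (published totals
include it); cells are percentages rounded half-up to 2 decimals, printed
ranges to 1 decimal, means to 2, mean length to the nearest integer. The
published table ships verbatim as a TSV fixture; its printed ranges
(glutamine 24.1–34.9 %, proline ≤ 11.0 %) hold over the non-D columns, and
the mean length of 223 is the mean over all 16 columns.

## Epitopes

Matching is exact against canonical forms plus explicitly listed observed
variants (no mismatch-tolerant search — each observed oat form is named);
overlapping occurrences all count, which is what makes `(PFVQQQQ)×3 PF`
contain three 9-mers. Per-haplotype totals are
Σ_family (copies per protein × genes in inventory); non-uniform per-protein
counts within a family are flagged and reported per gene. The
wheat/barley/rye comparison registry is not reproduced; `position_incidence`
takes a user-supplied aligned set (a clearly labelled synthetic demo set is
bundled), with gap columns excluded from the denominator at their position.

## Pipeline and scale choices

Every stage writes its intermediates; a rerun with the same config and seed
is byte-identical (the config hash excludes the output directory). The test
suite runs the full pipeline at 1,200 reads (~35× per locus) noise-free and
at 2 % substitution; the analysis scripts use 5,000 reads (~150×). Both
recover 100 % of planted loci with correct family, status, domain
boundaries (±3 aa) and epitope totals. Study-scale quantities that depend
on SRA-scale data or external databases (total locus counts across six
varieties, blastx match rates, GO annotation) are outside what the
synthetic conditions can or should reproduce.

## Known limitations

* The mapper has no base-level alignment; identity estimates are anchor
  coverage, biased low at high error rates.
* The consensus model is substitution-only; indel-heavy reads would degrade
  column placement (dropped bases, lower depth) before producing wrong
  calls, but true indel variants cannot be represented.
* Intron-bearing genes are only handled because the generator's introns are
  frame-neutral; real globulin annotation would need a spliced gene model.
* NJ topologies for deep, saturated pairs use a capped distance (3.0
  substitutions/site), which compresses those branches.
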