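# Methods

This note records the model implemented by `metabarcode`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Orthology and the core genome

Genes are compared at the protein level per genome pair. The built-in
search backend is a seeded Smith–Waterman: a query is aligned only against
subjects sharing at least 4 distinct amino-acid 4-mers (BLOSUM62, gap
open 11 / extend 1), and a hit is kept when its Karlin–Altschul expectation
value `E = K·m·n·e^{−λS}` (gapped BLOSUM62 constants λ = 0.267, K = 0.041)
is at or below 10⁻⁴. Reciprocal best hits are computed from a single
symmetric score table per genome pair; ties in raw score are broken by more
identities, then the lexicographically smaller gene id, so results are
deterministic. RBH pairs from all genome pairs are merged by union–find;
a cluster is *core* only when it holds exactly one gene from every genome —
clusters containing in-paralogs stay accessory because each core COG must
contribute exactly one sequence per genome to the codon alignment and the
barcode. The seed threshold trades sensitivity to distant homologs
(irrelevant at the within-genus identities the tool targets) for speed; an
external search tool can be substituted behind the same `ProteinHit`
contract.

CDS completeness filtering (length divisible by three, no internal stop,
start codon required unless `keep_partial`) is applied before clustering;
translation uses NCBI table 11 by default. All replicons, including
plasmids, are included.

## Codon alignment and the divergence axes

Core COGs are aligned at the protein level with a built-in center-star
progressive aligner (center = member with the largest summed global
alignment score; pairwise gap patterns merged under once-a-gap-always-a-gap)
and the gaps are threaded back onto codons, so gap columns are triplets and
degapping a row reproduces the gene exactly. Any multiple aligner can be
plugged in; the test suite cross-checks divergence statistics against MAFFT.

Per genome pair, over ungapped non-stop codon columns:

- X = sense nucleotide substitutions / all nucleotide substitutions, where
  a substitution is *sense* when its codon translates differently between
  the rows (all differing positions of such a codon count as sense; the
  no-substitution case defines X = 0). X is deliberately a simple
  proportion, not a dN/dS estimate — no pathway counting or multiple-hit
  correction is applied.
- Y = 1 − identical residue pairs / aligned residue pairs.
- Z = (positives − identities)/identities with positives = BLOSUM62 > 0
  (identities included), the BLAST "Positives" statistic; Z is defined 0
  and flagged when identities = 0.

X and Y are fractions on [0, 1]; the suitability score
X(1−X)(1−Y)/(Z+1) then lies in [0, 0.25]. COG-level values are unweighted
means over all genome pairs (the alternative — pooling columns across pairs
jointly — weighs long genes more and was rejected for transparency).

## Barcode assembly

`target_core_length = (1 − accessory_fraction) × requested_length`, default
accessory fraction 0.3. Core COGs are appended in descending score order
(ties: smaller COG id) until the *minimum* per-genome core length reaches
the target, which guarantees every barcode reaches it; genes come in whole
units, so barcodes overshoot by at most one gene and are never trimmed —
realized lengths are reported instead. Accessory genes are selected by a
greedy cover (largest number of still-needy genomes, then longer gene, then
smaller id) and each selected family contributes its gene to every carrier.
Genes are concatenated without spacers; reads spanning segment junctions
are accepted as a minor noise source.

## The binning score cascade

Alignment uses match +1, mismatch −2, gap open −5, gap extend −2, one best
hit per (read, barcode) pair over both strands, reported at raw score ≥ 30.
Seeds are exact 13-mers sampled every second read position; seeds agreeing
on one diagonal are scored by an exact vectorized gapless Smith–Waterman on
that diagonal, and disagreeing diagonals (an indel signal) fall back to the
full affine-gap DP on the implied window. On substitution-only data the two
paths give identical scores (asserted in the tests). The engine targets
short reads (roughly 100–500 bp); long noisy reads are out of scope.

The S′ filter uses the **pre-filter** pool statistics (S = mean raw score
over hits, L = mean aligned-read length, N = aligned reads) and is applied
once, not iterated. Degenerate inputs: with N < 2 the formula's lg N
denominator vanishes and filtering is skipped; when S approaches L
(near-perfect alignments) the formula exceeds every attainable hit score
and would empty the pool, so in that regime the filter is skipped with a
warning — real shotgun data with sequencing errors does not enter it.

Read specificity is the linear interpolant
`(N_barcodes − n_hit)/(N_barcodes − 1)` between its two defining endpoints
(1 for one barcode, 0 for all). Vicinity uses Jaccard distances
`1 − |A∩B|/|A∪B|` between post-filter read sets; an all-zero distance
matrix gives every read vicinity 0, and the ratio is evaluated
divide-then-scale so the bound r_vic ≤ 10 holds exactly in floating point.

Two readings of the barcode-score normalization were examined. Summing
length-normalized alignment scores **per barcode** (`T_i` over the reads
aligned to barcode i) and taking ReadScore2's read-count denominator as the
number of **aligned** reads makes both default cut-offs act as meaningful
thresholds: BarcodeScore1 then saturates at `(4/3)·N_barcodes·share − 1`
(so 2.3 ≈ "a handful of specific, well-scoring reads", reachable only with
≥ 3 barcodes) and BarcodeScore2 tracks the barcode's share of the aligned
pool (relative abundance). The alternative global sum drives BarcodeScore2
toward −1 for every barcode at realistic pool sizes, leaving the 0.5
cut-off unreachable, and was rejected; both switches remain available
(`score_sum_mode="global"`, `nreads_mode="total"`). Boundary calls use ≥ at
the cut-offs; paired reads are treated as independent single-end reads.

## Synthetic data

The generator emulates the validation design: families of genomes sharing
single-copy core genes at a controlled divergence. Ancestral genes draw
codons uniformly from the 61 sense codons (ATG start, single TAA stop);
each genome's copy receives amino-acid-changing single-nucleotide
substitutions at `(1 − p)/2` of its codons (p = target pairwise protein
identity, default 0.8 ≈ congeneric species) plus synonymous substitutions
to realize the sense/silent ratio (default 0.5), start/stop untouched.
Genes are embedded on random strands in uniform-random intergenic spacers
(mean 100 bp) in a per-genome random order. Accessory families are carried
with probability 0.5 per genome. Defaults: 8 genomes, 50 core + 20
accessory families, gene length ≈ N(900, 150) bp.

Metagenomes draw each read's genome by abundance, position uniformly,
strand at random, and length from a normal distribution truncated to
[200, 350] bp (mean 275, sd 25); substitution errors optional (default 0),
no indel or quality-profile error model, no GC bias, no paired ends.
Background reads beyond the requested abundances come from an extra family
member that never receives a barcode. A single integer seed fixes all
randomness; reruns are byte-identical.

What passing tests on these data show: correct orthology recovery, correct
score arithmetic, and correct present/absent discrimination when divergence
between panel members is uniform and reads are error-free. What they do not
show: robustness to annotation errors, horizontal transfer, rearrangements,
within-species mosaicism, or platform-specific error profiles of real
genomes and reads.

## Validation at desk scale and known limitations

The validation suite scales the original design down to one 8-genome panel
(20-kbp barcodes, 20,000-read metagenomes at 15/10/5/5% plus background) so
it runs in minutes on one CPU. At this scale a structural property of the
scoring becomes visible: BarcodeScore2 saturates near
`(4/3)·N_barcodes·(barcode's share of aligned reads)·a − 1`, which for a 5%
genome in an 8-barcode panel with four present members is ≈ 0.4–0.5 —
*at* the default 0.5 cut-off. The two 5% genomes are therefore missed by
BarcodeScore2 (BarcodeScore1 separates them from absent genomes perfectly;
the pooled BarcodeScore1 AUC is 1.0), and sensitivity at default cut-offs
can move when barcode length changes. In panels of 16–40 barcodes with few
present genomes — the regime the default cut-offs were chosen for — the
same genomes score well clear of the cut-offs. Users running small panels
should lower `cutoff2` or read the scores directly rather than the binary
calls.

Other limitations: no gene prediction (annotated genomes required), no
EMBL/GFF3 input, no synteny- or tree-aware orthology, no primer design (the
barcodes are in-silico references, not amplicons), and cut-off defaults
inherited from short-read validation — they are not calibrated for long
noisy reads.
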