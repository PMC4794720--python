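# Methods

## Characters and coordinates

A mutational event is a unique genomic change identified by
(chromosome, position, ref, alt) with 1-based inclusive coordinates and
VCF-style left anchoring for indels. The same site observed in several
strains — even in separate lineages — is *one* character; independent
origin is recovered later as multiple gains on the tree, which keeps the
character matrix and the homoplasy signal cleanly separated. Event type
is inferred from allele lengths (SNV, insertion, deletion); equal-length
multi-base substitutions must be decomposed upstream. Missing genotype
calls are not supported: a strain either carries an event or it does not.
Camin–Sokal scoring with unknowns is a different estimator, and catalogs
from clonal isolates at ~30× coverage are effectively complete.
Overlapping gene annotations are rejected rather than multi-assigned so
per-gene counts stay well defined; ORF overlap in compact microbial
genomes is rare enough that this costs little.

## Irreversible parsimony

The parental strain is the known all-reference genotype, so the root
state of every character is 0 and changes are directed 0→1
(Camin–Sokal). On a fixed rooted tree the minimum number of gains for a
character equals the number of maximal subtrees whose leaves all carry
the derived state; the gain edges are the edges above those subtrees'
roots. The test suite proves this against exhaustive minimization over
all internal labelings with the irreversibility constraint, on every
rooted binary topology with up to six leaves and every leaf pattern.

Serially sampled strains are represented as leaves even when one is the
literal ancestor of another; an ancestral genotype simply sits on a
zero-gain pendant edge. No unrooted analysis is offered — the root is
data, not a nuisance parameter.

Search proceeds in three regimes, all returning the set of optimal trees
up to a configurable cap (default 10 000):

* **exact** (n ≤ 8): every rooted binary topology is generated once by
  ordered leaf insertion and scored.
* **branch and bound** (default n ≤ 25): depth-first insertion of
  strains in decreasing mutation count, pruned with an admissible bound
  — the partial tree's score plus one future gain for every non-empty
  character none of whose carriers has been inserted yet. Restricting a
  tree to a leaf subset never increases a character's gain count, so the
  bound never exceeds the score of any completion and no optimum is
  pruned. Once the tie cap is full, branches whose bound *equals* the
  incumbent are also pruned (they can only add ties, never
  improvements); `cap_hit` reports the truncation. Strains with
  identical genotypes are collapsed to one representative before the
  search and re-expanded afterwards as a multifurcating clone cluster —
  duplicates cannot change the optimal score but make the tie set
  explode combinatorially.
* **heuristic** (any n): stepwise addition in seeded random order with
  greedy placement, then nearest-neighbour-interchange hill climbing to
  a local optimum; deterministic given the seed, score is an upper
  bound on the true optimum.

Ties are summarized by strict consensus (exactly the clades common to
all optimal trees) and propagated into convergence counts as min/max.

## Convergence statistics

For each gene, the statistic is the number of independent acquisition
*events*: the sum over the gene's mutations of their gain counts, so a
mutation arising on two branches contributes two. The headline number is
the minimum over the optimal tree set — a conservative lower bound, in
the same spirit as reporting "at least k events".

Two nulls are attached:

* **Exact binomial.** m catalog events placed uniformly on a genome of
  length L hit a gene of length l independently with q = l/L, giving
  P(≥ k) as the exact Binomial(m, q) upper tail (scipy's survival
  function; no normal approximation, stable at q ≈ 10⁻⁴). Treating each
  of the m events as one potential hit is conservative for events that
  gained more than once. Gene length is the annotated interval length —
  the null is deliberately uniform, with no mutational-opportunity
  weighting by composition or context.
* **Permutation.** Each permutation redraws every event's position
  uniformly on [1, L] (chromosomes concatenated), reassigns genes, and
  recomputes per-gene totals on the *fixed* tree set; leaf patterns, and
  hence per-event gain counts, never change — only gene labels move.
  p = (1 + #{permutation ≥ observed}) / (B + 1), plus a family-wise p
  from the max-over-genes statistic. Because positions are independent
  of presence patterns under the uniform null, this test is exactly
  valid for any fixed tree set, optimal or not.

Multiple testing uses Bonferroni over the annotated genes by default.
This is deliberately blunt: the discovery claim to protect is "this one
gene is exceptional genome-wide", and the binomial p-values in the
interesting regime are so extreme that the correction costs nothing.

## The stepwise simulator

`ale_sim` emulates the breeding protocol: Wright–Fisher reproduction
with multinomial offspring sampling proportional to fitness; within each
stage genotypes carrying at least one mutation in the designated driver
gene have fitness 1 and all others 1 − s; mutations arrive as a Poisson
process per genome per generation with positions uniform on [1, L] under
infinite sites (collisions redrawn); at each stage's end a fixed number
of isolates is sampled without replacement and emitted with the stage
temperature. All randomness flows from one seed through a
SeedSequence-spawned stream per stage. The full truth is recorded —
sampled genealogy (as a trie over ancestry paths), per-event origination
generation, driver identity — so the pipeline's recovery can be scored.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| genome_length L | 1.2 × 10⁷ bp | compact yeast-sized genome |
| pop_size N | 1000 | scaled-down stand-in for a laboratory culture; large enough for selection to dominate drift at s = 0.5, small enough to simulate hundreds of replicates |
| mut_rate μ | 0.004 / genome / generation | ≈ 3 × 10⁻¹⁰ per bp, the measured order for budding yeast; over 4 × 200 generations it yields strain catalogs of a few mutations each and experiment-wide totals of a few dozen |
| generations per stage | 200 | fixed duration replacing the original protocol's empirical "adapted" criterion, for reproducibility |
| selection s | 0.5 per stage | strong stress: non-adapted genotypes grow at half rate |
| driver_mut_rate | 5 × 10⁻⁴ / genome / generation | beneficial mutations enter through their own rate because at N = 1000 the genomic rate alone would essentially never hit a ~1.5 kb target within an 800-generation experiment, whereas real cultures are 10⁴–10⁶ times larger; this restores a realistic supply of driver alleles (and hence soft sweeps) at simulation scale |
| isolates_per_stage | 5 | a few clones per preserved population |
| indel_fraction | 0.1 | minority of events are indels |

Recurrent same-site mutation (true homoplasy at one position) does not
occur under infinite sites; it can be injected through the hotspot
parameters, which divert a configurable probability mass onto designated
positions. What the simulator does **not** model: mutation-rate
heterogeneity along the genome, structural variation, clonal
interference between multiple driver genes, quantitative growth-rate
surfaces (driver rescue is binary), or the possibility that an isolate's
genome is missequenced. Tests passing on these synthetics therefore
validate the inference machinery, not the realism of any particular
biological rate.

## Calibration and recovery experiments

*Permutation-test calibration.* The per-gene statistic is a small
integer count. At study scale (q ≈ 4 × 10⁻⁴) a gene is almost never hit
under neutrality, so a rejection-rate check at α = 0.05 would be
vacuous: the test would reject with probability ≈ P(≥1 hit) ≪ α, which
says more about discreteness than validity. The calibration experiment
is therefore sized so the null statistic has resolution: a 6 × 10⁵ bp
genome tiled into 9.5 kb genes, neutral stages (s = 0), μ = 0.02,
N = 200, chosen via a pilot (mean total gain count ≈ 50) so the tested
gene's expected count is ≈ 0.8. Under that design the rejection rate of
a valid test at α = 0.05 over 200 replicates at B = 999 falls inside the
95% binomial band around 0.05, and the acceptance suite verifies it does.

*Driver recovery.* With the default configuration (s = 0.5, four
stages, five isolates per stage) the driver gene attains the strictly
highest independent-gain count in ≈ 97% of pilot replicates (39/40,
pilot seed 314159). The acceptance test runs 25 fresh replicates and
requires a rate ≥ 0.80 (the pilot rate minus roughly three binomial
standard errors at that replicate count), along with the invariant that
the true genealogy never scores below the search optimum.

## Transcriptome stage

Fold change is (mean mutant FPKM + ε) / (mean parent FPKM + ε) with
replicate means taken first; ε defaults to 0.1 FPKM, large enough to
tame ratios of barely-expressed genes and small enough to leave
expressed genes untouched. With ε = 0, genes whose parent mean is zero
are excluded as undefined, with a warning. "Induced more than
1.5-fold" is a strict inequality on the ratio, no log transform. The
regulator attribution is 100 × |targets ∩ induced| / |induced| per
regulator against a user-supplied regulator→target table; regulators
overlap, so percentages need not sum to 100. Hierarchical clustering,
heat maps and functional enrichment are out of scope — established tools
already cover them.

## The packaged synthetic catalog

`datasets.synthetic_study_tables()` generates (deterministically) a
catalog with the shape of a real stepwise thermotolerance experiment:
19 strains over 32/34/36/38 °C, 49 events on a 16-chromosome 1.2 × 10⁷
bp synthetic karyotype, a 4758 bp minus-strand driver gene carrying four
distinct point mutations, one of them planted on two separate lineages.
Every internal edge of the generating genealogy carries at least one
marker mutation, so the most-parsimonious tree is unique and equal to
the truth (score 50 = 49 events + 1 extra gain of the recurrent site),
making the fixture an end-to-end regression oracle: driver gains_min is
exactly 5 and the recurrent site gains exactly 2 on every optimal tree.
It is a constructed test article, not a transcription of any published
mutation table.

## Numerical and degenerate-input notes

Bitmask scoring: clades are leaf-set bitmasks (taxa ≤ 64 after
duplicate collapse; search limits are far below that), and scoring is a
vectorized subset test over node × character mask arrays. All-zero event
columns are dropped at matrix build with a warning; a parental strain
carrying an event is an error, not a warning, because it breaks the
rooting assumption. Empty induced sets raise with guidance rather than
returning NaN percentages. p-values are clamped to [0, 1] after
Bonferroni. Newick output quotes labels containing metacharacters;
parsing is delegated to dendropy.

## Known limitations

* Branch and bound is worst-case exponential; highly homoplastic
  matrices (far from the ALE regime) should use the heuristic, which
  carries no optimality guarantee.
* gains_min/gains_max summarize only the retained tie set when the MPT
  cap truncates it (`cap_hit = True`).
* The binomial null conditions on m observed events and ignores
  per-gene mutational-opportunity differences; genes that are mutational
  targets for structural reasons will look falsely convergent under both
  nulls.
* VCF input reads genotype presence only (any non-reference call);
  likelihoods and filters must be applied upstream.
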