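# Methods

This note documents the models implemented in `matriline`, the defaults
and why they were chosen, the numerical choices, what the synthetic data
generator does and does not emulate, and known limitations.

## Coordinate frame and reference

All positions are 1-based on a single fixed control-region reference of
length 1232 bp; the frame covers the complete D-loop, so every bundled
diagnostic position (including 686) lies inside it with no offset. The
packaged reference (`data/synthetic_reference.fasta`) is **synthetic**:
a deterministic pseudo-random sequence whose bases at every diagnostic
motif position are pinned to the ancestral states implied by the motif
tokens of the bundled classification scheme. It exists so that the
classifier fixture, the simulator and the tests are self-contained; for
real data, pass the true chicken mitogenome control-region reference via
`--reference` / `load_reference`. A frame offset, if any, is absorbed by
supplying a reference whose position 1 is the first D-loop base.

## Anchoring and substitution scoring

Each input sequence is globally aligned to the reference
(match +1, mismatch −1, gap open −4, gap extend −1 — fixed constants, so
outputs are bit-reproducible). The per-reference-position state vector is
extracted from the aligned blocks; insertions relative to the reference
are stored on the record but excluded from the 1..1232 frame and from
every downstream statistic (a fixed-length frame admits no insertion
columns). IUPAC ambiguity codes are masked to missing *after* alignment
so they can inform placement but can never create a spurious motif
match. Sequences outside ±20% of the frame length, or below 70% identity
over called positions, are rejected as not resembling the target locus.
Ties between equally optimal alignments are resolved deterministically
by the aligner's fixed traversal order; the test suite checks optimality
of the achieved score against an independent affine-gap (Gotoh) dynamic
program rather than a particular traceback.

## Haplogroup classification

The haplogroup nomenclature is a rooted tree in a YAML config; nodes
carry the diagnostic motifs on their branch beyond the parent.
Classification uses cumulative-path semantics — a node is satisfied only
if the union of motifs from the root to that node is contained in the
sample's variant set — because diagnostic motifs accrue along branches
of a rooted tree. Consequences, chosen deliberately:

- **Back-mutation** at a diagnostic site breaks the path; the sample
  falls back to the deepest still-satisfied ancestor. Tokens present in
  the sample but diagnostic for branches off the assigned path are
  reported in `conflicts`; absent child tokens that blocked deeper
  assignment are reported in `missing`, so borderline samples are
  auditable.
- **Ties** between equally deep satisfied nodes return `unclassified`
  with both candidates listed, rather than an arbitrary pick.
- **Missing data** at a diagnostic position is non-matching (conservative
  assignment), surfacing in `missing`.

In the bundled scheme the token A281G — shared by the published V and
D1b cumulative sets — sits on the macrohaplogroup CDV branch, with
T355C/C363T on V, C296T on D, T306C on D1, and A342G/G686A on D1b; this
reproduces the published cumulative sets exactly while keeping each
sub-branch identifiable. Motifs for haplogroups whose defining tables
are not printed in a main text (A, B, C, E, F, V1, D1a, D2) are
synthetic placeholders, marked `source: synthetic-placeholder` in the
YAML; the classifier is entirely config-driven, so a real scheme table
drops in without code changes.

## Site policy, haplotypes, diversity

Default site policy is **complete deletion**: any site with a gap or
missing call in any sequence of the analysis set is excluded from
haplotype collapsing, S, and π (matching the default of the classical
haplotype-analysis tools). A pairwise-deletion option exists for π only;
its variance uses the mean pairwise site count as L. Haplotypes are
classes of sequences identical over included sites, labelled
`Hap_1, Hap_2, ...` in first-occurrence order.

Gene diversity uses Nei's unbiased estimator with his sampling variance
(the classical "eq. 8.12" form); nucleotide diversity uses the
no-recombination sampling variance ("eq. 10.7" form,
V = (n+1)π/(3(n−1)L) + 2(n²+n+3)π²/(9n(n−1))). Variable sites are
singletons when every minor state occurs exactly once, otherwise
parsimony-informative — a rule that keeps the binary arithmetic
singletons + PIS = S exact even at multi-allelic sites.

## Neutrality tests and the coalescent null

Tajima's D uses the standard a₁…e₂ constants; S = 0 returns NaN (flagged
"not computable"), never 0. Fu's Fs computes
S′ = P(K ≥ k_obs | θ = θ_π) under the Ewens sampling distribution with
unsigned Stirling numbers of the first kind evaluated by the log-space
recurrence |s(n+1,k)| = n|s(n,k)| + |s(n,k−1)| (logaddexp), numerically
stable past n = 350; the test suite verifies against exact
rational-arithmetic Stirling computation for small n. θ for the null is
θ_π by default (Fu's own prescription), with Watterson's estimator as an
option.

The null distribution comes from the package's own neutral
infinite-sites Kingman coalescent: waiting times Exp(k(k−1)/2) while k
lineages remain, mutations Poisson(θ/2 × branch length), every mutation
on a fresh site. Two exact samplers of the same process exist: an
explicit-genealogy simulator, and a vectorized summary path that tracks
per-lineage subtree sizes (for π), mutation counts (for S) and a
stem-class recursion (for the haplotype count K: merging two lineages
whose top segments are both mutation-free fuses their adjacent haplotype
classes). The two are cross-checked against each other, against the
analytic E[S] = θa₁ and E[TMRCA₂] = 1, against the exact Ewens K
distribution (χ² goodness of fit), and against an independent coalescent
implementation (msprime) in the test suite.

p-values use the (b+1)/(m+1) permutation convention and are reported two
ways: one-tailed on the side of the observed sign (the convention of the
classical packages), plus the fixed lower-tail probability
P(stat_sim ≤ stat_obs). Calibration statements (type-I error 5%) apply
to the fixed lower-tail test — the standard "significantly negative"
reading; the sign-switching convention necessarily doubles the null
rejection rate and is reported for interoperability, not calibration.
Replicates with undefined statistics (S_sim = 0 for D) are excluded from
that statistic's tail count.

## Population structure

AMOVA follows the Excoffier–Smouse–Quattro sums-of-squares decomposition
on the matrix of raw pairwise differing-site counts (used directly as
squared distances — the haplotype-data convention; model-corrected
distances are out of scope). Negative variance components are reported
as computed, not zeroed, so percentages can leave [0, 100] on
near-panmictic data. Permutation schemes per level: sequences among
populations (Φ_ST), sequences among populations within groups (Φ_SC),
whole populations among groups (Φ_CT). Pairwise Φ_ST is the
two-population single-group AMOVA index; its permutations shuffle
individuals between the two populations and are evaluated through a
quadratic-form identity (within-group sums as z′D²z/2), which turns
10,000 permutations into two matrix products. Populations with fewer
than two sequences are excluded from the pairwise matrix with a record.

PCoA is classical Gower double-centering of the elementwise-squared
Φ_ST matrix with eigendecomposition; coordinates are eigenvectors scaled
by √λ over positive eigenvalues, percent variation is relative to the
positive eigenvalue mass. Tools differ in standardization details, so
axis percentages from other software may deviate by ≲1%.

## Median-joining networks

Construction: (1) an ε-relaxed minimum spanning network over Hamming
distances — an edge of weight w is admitted iff its endpoints are in
different components of the graph of admitted edges of weight ≤ w−ε−1;
ε = 0 (the default, as in the classical software) yields exactly the
union of all minimum spanning trees; (2) quasi-medians of connected
triplets (per-site majority; a site where all three states differ spawns
all variants, capped at 64 per triplet with an error on overflow) are
added greedily while they strictly reduce the spanning cost, to a
fixpoint with a 50-round cap; (3) median vectors not on any shortest
path between observed haplotypes, or of degree ≤ 1, are pruned. All
variable sites are weighted equally. On homoplasy-free data the result
is a tree achieving the exact Steiner (parsimony) length — verified
against a Dreyfus–Wagner exhaustive search for small instances.

Haplogroup separation (`mutation_steps`) is the minimum shortest-path
distance over node-set pairs. The ρ utility converts the size-weighted
mean mutational distance from a designated root into years via
tmrca = ρ/(rate·L) with the control-region clock 3.13×10⁻⁷
substitutions/site/year by default. It is a rough founder-age heuristic:
not comparable to calibrated Bayesian node ages, and labelled as an
approximation in outputs.

## Synthetic data generator

`generate_dataset` emulates a multi-country control-region survey:
founder haplotypes are the reference plus each haplogroup's cumulative
motif path; each deme draws a fixed haplogroup composition
(largest-remainder apportionment, so compositions are exact); within
each deme × haplogroup group, private substitutions are overlaid from
the package's own coalescent at `theta_within`, mapped to positions
disjoint from all diagnostic motif positions (classification truth stays
exact by construction); optional deme-private divergence substitutions
and migrant haplotype copying between demes (sources restricted to
non-migrants, so copies never chain). Everything derives from one seed.

The bundled survey-scale spec (7 demes, N = 509) mirrors the sampling
design of Southeast Asian/Pacific surveys: per-country deme sizes
(173/63/25/78/135/24/11), the ancestral D2 lineage concentrated in
Cambodia (~39%) and absent from Myanmar, F prevalent in Myanmar, V/V2
confined to the Mekong demes, D1b dominating the island demes, a 17.3%
migrant share producing transregional haplotype sharing, and
`theta_within = 3` (per-locus), which puts per-site π in the
0.004–0.008 range typical of these data.

What the generator does **not** emulate: structured-coalescent
migration (copying is instantaneous sharing, not gene flow with drift),
recombination (correctly absent for mtDNA), back-mutation/homoplasy at
diagnostic sites (excluded by default so truth recovery is exact —
injected deliberately in tests that probe the classifier's fallback),
sequencing error, indel polymorphism, and rate heterogeneity along the
molecule. Passing tests therefore demonstrate algorithmic correctness on
clean, frame-consistent data; they do not certify robustness to
alignment ambiguity or homoplasy in real surveys.

## Pipeline and reproducibility

Stages run in dependency order (score → classify → diversity →
neutrality → structure → network); each stage's seed is spawned from the
master seed via `numpy.random.SeedSequence`, and the manifest records
package version, parameters, per-stage seeds and SHA-256 checksums of
all inputs and outputs — two runs from one config are byte-identical.
Presentation tables round Hd/π to 3 decimals; a parallel
`diversity_full.tsv` keeps full precision. Pooled region rows aggregate
sequences (not averages of per-population indices).

Default problem sizes: 10,000 permutations for pairwise Φ_ST and 1,000
for AMOVA (classical defaults); 1,000 coalescent replicates for
neutrality p-values. The acceptance script and the end-to-end tests use
1,000/200/500–1,000 respectively on the N = 509 synthetic survey — sizes
chosen as ample for the Monte-Carlo resolution those checks assert.

## Numerical and degenerate-input choices

- Tolerances: cost comparisons in median insertion use 1e-9; PCoA
  positive-eigenvalue threshold is 1e-12 relative to the spectral radius.
- Hd/π variances are clamped at 0 before the square root.
- Monomorphic data: Hd = π = 0; Tajima's D is NaN; Fu's Fs with
  k_obs = 1 is +∞ (S′ = 1); neutrality p-values refuse monomorphic input
  (null θ = 0).
- Φ/AMOVA with zero total variance return NaN rather than 0.
- Tie-breaks are deterministic everywhere (sorted iteration orders), so
  all outputs are reproducible bit-for-bit under a fixed seed.

## Known limitations

- Pairwise-deletion π uses an averaged L in its variance; complete
  deletion is the supported policy for haplotype collapsing and S.
- The MJ median-insertion search is greedy per round; it attains the
  Steiner optimum on homoplasy-free data (tested exhaustively at small
  sizes) but, like all MJ implementations, is heuristic under homoplasy.
- The quasi-median variant cap (64 per triplet) errors out rather than
  silently truncating on pathological triplets.
- Real-data reproduction of published survey tables requires the real
  reference and the deposited sequences; the bundled reference and
  placeholder motifs are for self-contained validation only.
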