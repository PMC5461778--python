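# Methods

`aptastack` analyzes HT-SELEX sequencing data for RNA-protein
interactions whose recognition motif is a *substructure* — a stack of
base pairs — rather than a contiguous sequence motif.  This note
documents the models and procedures, the choices made where the design
was genuinely open, and what the synthetic data does and does not show.

## Template and read filtering

The selection library is an 87-nt aptamer: a 15-nt 5' PCR primer
(`TGCGTAACGTACACT`), a 30-nt randomized region, a 27-nt constant region
(`TCATTCTATATACTTTGGAGTTTTAAA`) and a 15-nt 3' primer
(`ATGTCTCTAAGTACT`).  Reads are accepted when (in this order, so each
rejection has one reason): the forward-strand primer pattern is present;
only A/C/G/T occur between and including the primers; every base's PHRED
score (Sanger +33) is at least 20; the primer-delimited insert is 79-100
nt; and the T7 promoter 17-mer occurs at most once (two or more copies
mark a "rapid amplifier" PCR artifact).  Only single forward reads are
used — no mate merging, no reverse-complement rescue.  The length rule
is applied to the primer-delimited insert.  Counts are normalized to the
round's usable total.

## Clustering

Sequences are grouped CD-HIT style: visited in descending total-count
order (ties broken by a seeded shuffle), each joining the first existing
cluster whose seed lies within `1 - identity` normalized Levenshtein
distance, computed on primer-stripped cores.  The default identity is
0.85; 0.90 (the empirical separation point between related and unrelated
sequences) is available as an alternative.  Unit-cost Levenshtein
approximates CD-HIT's alignment scoring; small discrepancies on gapped
variants are expected.

Implementation: because every core shares the identical 27-nt constant
region, k-mer-count prefilters have no pruning power here.  Instead an
exact sparse neighbor graph (all pairs within the threshold) is built
once per sequence set using a bit-parallel bounded Levenshtein (common
prefix/suffix stripped — exact for unit costs — then Myers' algorithm
with early abandon).  Greedy assignment with any visiting order then
only consults neighbor lists, which also makes the five-fold
reclustering of the stability analysis cheap.  The graph formulation is
provably equivalent to the first-fit scan and is tested against one.

Cluster enrichment between a late round X and an early round Y is

    E = (n_cluster,X / N_X) / (n_cluster,Y / N_Y)

with N the per-round usable totals.  The minimal attainable enrichment
of a two-sequence cluster (one read per compared round) is N_Y / N_X;
"enriched" requires exceeding it strictly, "depleted" requires E < 1,
clusters between are excluded, and clusters missing a compared round are
excluded rather than assigned infinite ratios.

## Secondary structure

Two interchangeable backends provide MFE structures, centroid structures
(pairs with ensemble probability > 1/2) and base-pair probability
matrices:

* the **reference backend** — canonical pairs {AU, UA, GC, CG, GU, UG},
  minimum hairpin loop 3, one stability unit per pair, Boltzmann
  ensemble at unit temperature (weight e per pair).  MFE by
  pair-maximization with a deterministic tie-break (prefer the pairing
  branch, then the 5'-most partner); probabilities by inside/outside
  recursions (the outside pass runs in O(n^3) by accumulating enclosing
  pair contributions incrementally).  It is verified cell-for-cell
  against exhaustive structure enumeration for short sequences, which is
  the reason it exists: every downstream claim can be checked against a
  closed, enumerable model.
* the **vienna backend** — the ViennaRNA thermodynamic model, when its
  python bindings are importable.

The ensemble distance between equal-length sequences A and B is
`(1/|A|) * sum_{i<j} (P_ij^A - P_ij^B)^2`.  Unequal-length pairs are
skipped and counted, a documented limitation.  Folding always uses the
entire insert including primers and constant region.

## NCM extraction and enrichment

A 2_2 nucleotide cyclic motif is a stack of two adjacent base pairs —
strict adjacency, so bulges and internal loops break stacks; a 3_3 NCM
is three consecutive pairs, with overlapping windows.  Labels read the
stacked pairs from the 5' end, each pair 5'-base first (`AGG/CCU` duplex
= AU/GC + GC/GC).  Orientation-symmetric labels are *not* merged.

Per-round NCM frequencies: sample `sample_size` distinct sequences
without replacement, fold each (MFE by default), normalize each
sequence's stack counts to its own total (structure-free sequences
contribute zero vectors but remain in the denominator), and average.
Enrichment is the per-resample log2 frequency ratio between rounds,
reported as mean ± SE over 11 resamples.  A label absent from one side
of a resample receives a pseudo-frequency of half the smallest nonzero
per-sequence contribution in that resample and is flagged — this keeps
ratios finite while marking low-support ("spurious") labels.

Significance: a label is **enriched** when its late-vs-early ratios
exceed its late-vs-background ratios by a one-sided Wilcoxon rank-sum
test at p < 0.001 (exact at 11 resamples; the attainable minimum is
1/C(22,11) ≈ 1.4e-6) *and* the mean ordering agrees; **depleted** by the
opposite tail; **spurious** when the nominal ratio is large (≥ 1 log2
unit by default) without background support.  The background comparison
is what separates selection from composition: a sampled-composition
background shows how often a stack arises in random sequences with the
selected pool's base frequencies.  Critically, the background set is
**regenerated with a distinct derived seed for every resample** — with a
single shared background pool its finite-sample offset from the
sequenced pools is coherent across resamples and the rank-sum test
separates on noise (measured: false enriched calls in essentially every
selection-off run).

## Background simulation

Background aptamers are primers + a simulated 30-nt variable region
(uniform `BG_uni` or pool-derived `BG_samp` base frequencies) + a
simulated constant region.  The constant-region mutation model (per-site
rate; point/insertion/deletion mix; substitution outcomes; insertion
bases, defaulting to the substitution-outcome marginal) is estimated
from the final round.  Simulation draws the number of events from
Poisson(rate × 27) truncated at 27, places them uniformly without
collision, and applies them left-to-right (insertions after the site,
deletions of the site's base).

Estimation localizes the constant region by infix-aligning the full
27-nt reference into the primer-stripped core, then snapping the start
to the designed 30-nt variable length when within 4 nt of it.  The
snapping matters: at a free alignment flank a mutated head base is
equally well explained as a deletion, which biases the category mix
(measured before the fix: deletions overcounted by ~0.03).  The
per-site rate is estimated from all aligned events; the
category/outcome distributions from single-event sequences only, since
minimum-cost alignments of multi-event sequences can merge adjacent
events (a substitution beside a deletion reads as one deletion) while a
lone event is unambiguous and, events being independent, an unbiased
draw from the mix.  The
spec-style sliding-window localization (window 20, leftmost minimizer)
is retained as `locate_variable_region` — with a 20-nt window against a
27-nt reference any interior substring ties at distance 7, so the
leftmost rule normally lands on the true start, but head mutations can
shift it; it is not used for model estimation.

## LASSO selection of enrichment predictors

Clusters with more than `min_cluster_size` distinct sequences and reads
in both compared rounds become design rows: predictors are the mean
per-sequence normalized NCM frequencies over up to 500 sampled members
(matching the per-sequence normalization used everywhere else and
bounding folding cost); the label is 1 for enriched (ratio strictly
above the two-sequence minimum), 0 for depleted (ratio < 1); rows are
balanced 1:1 by seeded downsampling.  The L1 penalty is chosen by
10-fold stratified cross-validated log-loss with the one-standard-error
rule (the most regularized model within one SE of the best).  Log-odds,
95% CIs and p-values come from an unpenalized logistic refit on the
active set; these are naive post-selection values and labeled as such;
complete separation is flagged and CIs reported unbounded.  Because
greedy clustering depends on visiting order, the selection is repeated
over 5 reclusterings and predictors are retained when active with
p < 0.01 in at least 3 of them.

A binder-vs-background classifier fits a plain logistic regression on
per-sequence NCM frequencies restricted to the selected labels
(negatives default to `BG_samp` at 1:3), reporting stratified
cross-validated AUC.  A mid-round enrichment model can be scored against
late-round labels of the same clusters, averaged over reclusterings.

## Binding assays

Fraction bound is `Fb = counts_nc / (counts_nc + counts_nylon)`.  The
Hill equation `Fb = Min + (Max-Min) / (1 + (Kd/[P])^n)` is fit by
bounded trust-region least squares (Kd > 0, n > 0, 0 ≤ Min ≤ Max ≤ 1 —
the fraction bounds are a choice; unconstrained fits can wander
negative).  Starting values: Kd at the interpolated half-saturation
concentration (in log-concentration), n = 1, Min/Max at the observed
extremes.  At least 5 positive-concentration points spanning a decade
are required; zero-concentration points are excluded from the ratio
term.

## Synthetic SELEX generator

The generator emulates the sequenced experiment: four sequenced rounds,
selection acting multiplicatively on whole sequences
(f ← f·s, renormalized, between sequenced rounds — the first configured
round is the unselected snapshot), multinomial read sampling to the
round's pool size, and artifact reads (rapid amplifiers with duplicated
T7 promoters and in-band insert lengths; ~79-nt fragments from an 8-nt
variable-region deletion; low-quality reads).  Scaffold founders embed a
requested chain of 2_2 stacks in a stem-loop, extend the helix with
random pairs, and are accepted only when the reference backend's MFE
structure of the *full insert* contains every requested label; lineage
variants mutate only non-stem variable positions.  Determinism: one
master seed drives everything; identical configs give byte-identical
FASTQ.

Fixture scale used by the acceptance tests (scaled-down study
conditions): pools of 2×10^4 reads per round, resamples of 5×10^3
distinct sequences, 11 resamples, background sets of 3×10^3 per
resample, 20 replicates per condition.  The planted condition carries a
GU/UG wobble stack (the experimentally enriched NCMs are
wobble-containing) in 100 scaffold lineages at selection coefficient 8
from a rare start, against 100 unselected lineages and random
background; carrier and neutral lineages draw their stems from the same
pair distribution (wobble-weighted) and the same pad alphabet, so the
enriched/depleted cluster classes differ systematically only in the
planted stack — without this the post-selection logistic refit separates
perfectly and its p-values are undefined.  The selection-off condition
uses an effectively infinite random library (1.5×10^5 founders), making
each round an independent draw like the background, which is both the
realistic regime (the real pools are ~95% singletons) and the one in
which the rank-sum null is calibrated.

What passing synthetic tests show — and what they do not.  They show the
pipeline recovers planted selection on stacks under the reference
folding model, with calibrated false-call behavior when selection is
off.  They do not show that the thermodynamic folding of real aptamers
is captured (the reference model over-pairs relative to Turner
energies), nor do they reproduce the original experiment's specific
enrichment values, coefficients or AUCs, which require the unpublished
raw reads.

## Numerical and degenerate-input policies

Sanger PHRED+33 only.  Reference-backend partition functions are exact
float64 sums; sequences beyond ~200 nt would overflow and are out of
scope (the template is 87 nt).  Rank-sum tests use the exact method.
Empty pools, single-class designs, fewer than 3 resamples, unequal-length
ensemble comparisons and zero-signal binding points raise informative
errors rather than returning sentinel values.  Ties in cluster
abundance, LASSO fold assignment and downsampling all flow from explicit
seeds.
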