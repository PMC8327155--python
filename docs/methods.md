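# Methods

This note documents the models, estimators, parameter choices and known
limitations of the package. Everything quantitative stated here is
computed by the test suite or the `analysis/` drivers; nothing is quoted
from elsewhere.

## Calibrated trees

A `CalibratedTree` is a rooted, leaf-labelled tree whose node ages are
derived from branch lengths: age(node) = max root-to-tip distance − depth
of the node, so leaves sit at age 0 and the root age equals the common
root-to-tip path length. Ages are not read from annotations because
Newick has no standard age field. Trees whose tip depths spread by more
than a relative 1e-6 are rejected (naming the offending tips) rather than
silently reconciled; float noise within that tolerance is snapped so
leaves sit exactly at age 0 (slicing at age 0 must return one clade per
leaf). Units are whatever the branch lengths carry (the analyses use an
arbitrary "Mya-like" scale; only relative ages matter).

The external-calibration bookkeeping type records the outgroup 16S
sequence sets used to carry age calibrations when dating such a tree
(by default 50 Cyanobacteria + 50 Rickettsiales + 15 *Chlorobium* + 15
Chromatiales = 130 sequences, removed again before analysis). Building
or dating trees is out of scope: calibrated trees are consumed, not
produced.

## Ancient-DNA authentication

**Damage profile.** The 5′ C→T rate at read positions 1–10 is the ratio
of observed C→T mismatches to C-reference sites per position. The decay
fit `rate(i) = p0·exp(−λ(i−1)) + baseline` is weighted least squares
with weights equal to the per-position C-site counts.

**Degradation score.** A per-read log-likelihood ratio over the 5′
C-sites: a C→T at position i contributes `log(rate_i/baseline)`, an
undamaged C contributes `log((1−rate_i)/(1−baseline))`; other positions
contribute nothing. Rates are clamped to [1e-6, 1−1e-6] to keep the
ratio finite when a profile position is empirically 0 or 1. The score is
additive over positions and antisymmetric under swapping model and null.
The published per-read score additionally models 3′ G→A and base
qualities; this 5′-only form is a documented simplification, and the
"score > 1" screening threshold is configurable for that reason. Whether
its score-passing counts match published counts cannot be checked
without the original reads.

**−Δ%.** For an edit-distance histogram n_0..n_k, the proportion of
declining adjacent steps: `Σ max(0, n_i − n_{i+1}) / Σ |n_i − n_{i+1}|`.
A flat histogram has no steps and returns 0 with a warning. When a
screening row is built from read records, the histogram is restricted to
score-passing reads — matching the convention that C→T% and −Δ% are
computed on damage-supporting reads — and uses the deamination-discounted
edit distance (5′ C→T mismatches are damage-consistent, not alignment
error). Without the discount, score-passing reads would by construction
carry ≥ 1 mismatch and the histogram could never decline from zero,
contradicting the −Δ% = 1 values the published tables report on exactly
those reads.

**Screening.** Bacterial rule-set: assigned reads strictly > 500,
damage-supporting reads ≥ 50, −Δ% strictly > 0.9, any observed 5′ C→T
(rate > 0, floor configurable since no cutoff is published). The ≥ on
the damage-read count is deliberate: the published table contains a row
with exactly 50, which a strict inequality would reject. Dietary
(eukaryote mtDNA) rule-set: reads > 100, −Δ% > 0.9, C→T present; no
damage-read-count criterion. All 56 published bacterial rows and all 3
dietary rows pass their respective rules (asserted in the tests).

## BDTT

Slicing assigns each leaf to the node whose branch spans the cut age
(age(node) ≤ t < age(parent)); collapse sums member-leaf counts per host,
conserving per-host totals at every age. Per slice, the Sørensen
dissimilarity between hosts is correlated with each host factor by a
Mantel test. Design choices:

* **Slice ages.** No canonical grid exists; the drivers use
  {0, 100, 300, 500, 700, 900} on a depth-1000 tree, and the pipeline
  default is an even grid from 0 to the root age. A slice at/above the
  root collapses all hosts onto one clade and is reported as NaN rather
  than an error.
* **Mantel.** Pearson on the condensed upper triangles, two-sided on
  |r| (one-sided selectable), p = (1 + hits)/(B + 1). For n ≤ 8 hosts
  all n! permutations are enumerated instead — deterministic, exact, and
  immune to the Monte-Carlo noise that matters when a p-value sits near
  a tie floor (binary presence patterns produce heavy ties).
* **Envelope.** 95% credibility band of R² across host-label shuffles of
  the factor matrix. The historical protocol used 10 shuffles, for which
  min/max is the only sensible 95% rule; the default here is 1000
  shuffles with empirical 2.5/97.5 percentiles, because 10 draws cannot
  resolve a 95% interval. Below 40 shuffles the min/max rule applies.
* **Leaf-shuffle null.** Permutes leaf labels inside the tree, keeping
  its shape and the abundance table; leaf-level (age-0) correlations are
  provably unchanged (the tests assert exact equality) and deeper slices
  degrade toward noise when the observed profile carried genuine
  phylogenetic structure.
* **Per-lineage test.** The response/predictor arrangement is not fixed
  by any published description; here the response is the single clade's
  presence-mismatch distance between hosts and the predictor the factor
  matrix, with a pseudo-F `= R²/(1−R²)·(m−2)` over the m host pairs.
  Because the pseudo-F is a monotone map of R², its one-sided permutation
  p equals the two-sided-|r| Mantel p, and one shared permutation null
  drives all clades in a slice-factor stratum (vectorised). BH is the
  FDR procedure. **Limitation:** with 10 hosts the permutation p floor
  from label ties is ~0.005, so over a stratum of ~100 mostly-null clades
  BH-FDR ≤ 0.05 is structurally out of reach; the analysis driver
  therefore reports raw-p and FDR-adjusted counts side by side. Published
  hit counts at real-data scale (thousands of taxa) are not reproducible
  at desk scale and are not targeted.
* **Ward/Spearman clustering.** Profile distance 1 − ρ (average ranks
  for ties), Ward linkage, flat clusters at a configurable count;
  constant profiles are dropped with a warning. Cluster–factor coherence
  is assessed with the same Mantel machinery.
* **Ordinations.** Unweighted UniFrac and PERMANOVA are delegated to
  scikit-bio (the tests verify UniFrac against a branch-enumeration
  oracle on ≤ 8-leaf trees); PCoA double-centres the squared distances
  and eigendecomposes, returning positive-eigenvalue axes and reporting
  negative eigenvalues untouched. The Procrustes test superimposes two
  configurations (translation/scaling/rotation, reflection allowed) and
  permutes row order for its p-value.

## Diet-niche prediction

Diet distances are Euclidean over food-category consumption fractions.
Taxon selection is a per-taxon Mantel between the taxon's host-pair
presence-mismatch distance and the diet matrix at p ≤ 0.05 (an optional
BH adjustment is off by default — the selection-then-count convention
this mirrors reports unadjusted retention). The classifier binarises the
selected table, column-centres without scaling (PCA on presence/absence
has no natural variance normalisation), takes axis 1 (sign-fixed so the
largest-magnitude loading is positive), and fits a logistic regression
of class on the axis-1 score with a weak ridge (C = 100) so the
maximum-likelihood divergence under perfect separation — likely with 9
hosts — stays finite without moving threshold-0.5 decisions. Class
weights are balanced: with 4 wolves vs 5 dogs, an unbalanced prior
otherwise dominates the intercept and biases held-out predictions toward
the training majority (shuffled-label accuracy sat near 0.33 instead of
0.5 without it). Probability ≥ 0.5 assigns the omnivorous class; the tie
at exactly 0.5 goes to omnivorous (documented, not principled — no
convention is published).

Cross-validation enumerates every hold-out of size 1 and 2 (45 splits at
n = 9) and refits the *entire* procedure — selection included — inside
each training fold, so no information leaks from held-out hosts; the
leakage-prone variant (select once on all hosts) is available behind an
explicit flag for comparison only. Splits whose training set loses a
class, or retains no taxa, are skipped and reported. On fully separable
two-block synthetic data the accuracy is 1.0; under label shuffling it is
centred on 0.5 (both asserted in the tests).

## Copy-number estimation

The observable is the ratio r = target/(target+control) mapped reads,
with a Wilson score interval (chosen over Wald for small-count
behaviour; no specific interval flavour is published). Copy numbers are
obtained by anchoring: wolves are assigned CN = 2 and a single scaling
factor maps the anchor group's mean onto that value, making the anchor
mean exact by construction (the per-host-mean-factor alternative is
selectable). Two deliberate departures from a literal "scale the ratio"
reading, both documented because the literal form fails its own
consistency checks:

* **Odds linearisation (default).** Under Poisson read sampling,
  target ∝ CN and control ∝ 2, so the *odds* r/(1−r) — not r — is
  proportional to CN; the raw ratio saturates (CN 8 at equal effective
  lengths gives r = 0.8, and a CN-2-anchored ratio scaling estimates
  3.2, not 8). `linearize=False` restores the literal convention, which
  is adequate only while target reads are a small fraction of the total.
* **Anchor-variance propagation.** The scaling factor is estimated from
  four wolves and its noise is shared by every estimate; ignoring it,
  the CN-8 interval covered ~84% in simulation instead of ~95%. The
  delta-method relative variance of the anchor mean odds is folded into
  each host's interval on the log scale. With it, simulated coverage of
  the true dog copy number is ~95% (asserted ≥ 93% over 200 runs).

Length normalisation between target and control regions is available but
off by default (the ratio convention is a raw-count one). Read mapping
and quality filtering are upstream concerns; this module consumes counts.

## Synthetic data

The generators define the study conditions: 4 wolves, 5 modern dogs, 1
ancient sample; a 160-taxon bacterial tree of depth 1000; damage
amplitude p0 = 0.2 with decay λ = 0.4 over baseline 0.01; an amylase-like
coverage design (7,525 bp target, 75 × 1 kb control windows, 0.02
reads/bp per copy; wolves CN 2, dogs CN 8, ancient CN 2). Every generator
is a pure function of its frozen spec, seed included; composite scenarios
derive per-stream sub-seeds from one global seed.

**Trees** are random sequential-merge ultrametric trees: uniformly random
pair joins (Yule labelled-history topology) with merge ages sorted
uniforms on (0, depth), the root pinned at depth exactly. A pure-birth
merge-time law would differ only in the age distribution, which none of
the downstream analyses are sensitive to — only relative node ages enter
BDTT.

**Communities** plant the scale disparity directly. Mid-sized deep clades
(older than 500, between 2 and 20% of taxa each) are recruited until
~35% of taxa sit in an "ecology clade", alternately preferring wolves or
dogs: a preferred host carries the clade with probability 0.95·s + 0.5·(1−s)
(s = ecology strength), an off-group host with 0.05·s + 0.5·(1−s), the
ancient host at the midpoint; a carrying host holds a random ~35% subset
of the clade's members, so the group signal lives at the clade level and
is diluted by fill noise at the tip level. Every other taxon's occurrence
probability falls off linearly with host cophenetic distance from a
random focal host (0.95 at the focal host to 0.05 at the farthest,
blended with the baseline by the phylogeny strength) — a linear kernel
because with 10 hosts an exponential kernel leaves most host pairs in
its flat tail and the planted signal becomes undetectable. At strength
(0, 0) occurrence degenerates exactly to i.i.d. Bernoulli(baseline).
Occupied cells get log-series abundances (Sørensen only uses presence,
but the tables should look like count data). Group labels are assigned
to host-tree tips in random order so ecology is unconfounded with host
phylogeny by construction. Under the default strengths (0.8/0.8) the
BDTT profile recovers the planted disparity — phylogeny R² above its
envelope at young slices and ecology R² at deep slices — in 19 of 20
seeds, with the monotone young-vs-old trend in 20 of 20.

What the generator does **not** emulate: sequence-level reads (no
FASTQ), compositional count noise from sequencing depth, contamination
mixtures, correlated taxon co-occurrence beyond the planted structure,
or functional profiles. Passing tests therefore demonstrate that the
estimators recover the structure they target under a clean generative
model, not that they are robust to every artefact of real coprolite
data.

## Problem sizes and numerical choices

The suites run at deliberately desk-friendly sizes: 160 taxa × 10 hosts
for community analyses, 999 permutations (exact enumeration below 9
objects), 1000 envelope shuffles, 500 replicates for null-calibration
checks, 50,000 reads for damage-parameter recovery, 200 simulations for
interval coverage. Permutation p-values use the add-one convention
(1 + hits)/(B + 1) and so never fall below 1/(B + 1); tie comparisons
use a 1e-12 slack. Spearman ties get average ranks. PCoA treats
eigenvalues below 1e-10·max as zero. The logistic fit is deterministic
(lbfgs, fixed penalty); all permutation machinery is seeded through
`numpy.random.SeedSequence` spawning.
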