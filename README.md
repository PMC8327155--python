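# coproscope

Analysis toolkit for coprolite paleomicrobiome studies: given shotgun
metagenomes of ancient feces alongside modern reference hosts, it answers
four questions that recur in this field —

1. **Are the microbial assignments ancient?** Per-read and per-taxon
   ancient-DNA authentication statistics: positional 5′ C→T deamination
   profiles, a post-mortem degradation score (log-likelihood ratio of a
   damage model against an undamaged null over the first ten 5′ bases),
   the negative difference proportion (−Δ%) of edit-distance histograms,
   coverage depth/breadth, and configurable pass/fail screening rules.
2. **Which parts of the microbiome track host phylogeny vs. host
   ecology?** β-diversity through time (BDTT): the time-calibrated
   bacterial tree is cut at successive ages, taxa are collapsed into
   slice-defined clades, and each slice's Sørensen dissimilarity is
   correlated (Mantel) with host cophenetic and host-ecology distances,
   with label-shuffle credibility envelopes, a leaf-shuffle null, a
   per-lineage pseudo-F + BH-FDR association test, Ward/Spearman
   clustering, unweighted UniFrac, PCoA, PERMANOVA, and a Procrustes
   phylosymbiosis test.
3. **What did the host eat?** A microbiome-based diet-niche classifier:
   diet-correlated taxa (Mantel against a Euclidean diet-distance matrix)
   → presence/absence PCA → binomial logistic regression on the first
   axis (0 = carnivorous wolf-like, 1 = omnivorous dog-like), with
   exhaustive leave-1-out/leave-2-out cross-validation.
4. **How many copies of a host gene?** A read-depth copy-number estimator
   for a duplicated gene (the motivating case is canine AMY2B): the
   target/(target+control) read ratio with Wilson binomial intervals,
   linearised through the target:control odds and anchored on a
   calibration group of known copy number (wolves, CN = 2).

Because the raw sequence archives are outside desk scale, every stage is
exercisable on synthetic data of known structure generated by
`coproscope.simulate`: random ultrametric trees, host-structured
communities with a *planted phylogenetic scale disparity* (shallow clades
track host phylogeny, deep clades track host ecology), reads with
exponentially decaying 5′ damage, and Poisson region counts at known copy
number. The package also ships the published per-taxon screening tables
for the Solarolo coprolite dataset (56 gut bacteria, 3 dietary
eukaryotes) as worked examples.

## The statistics in brief

* Sørensen dissimilarity `d = 1 − 2a/(2a + b + c)` on presence/absence
  (a shared, b/c unique taxa); unweighted UniFrac = unique branch length /
  total branch length over the union of present taxa.
* Mantel test: Pearson r between condensed distance matrices;
  permutation p `(1 + #{|r*| ≥ |r|})/(B + 1)`, with exact enumeration of
  all n! label permutations when n ≤ 8.
* BDTT envelope: 95% band of R² under host-label shuffles of the factor
  matrix (min/max under the historical 10-shuffle protocol, empirical
  2.5/97.5 percentiles at the default 1000).
* Degradation score: `Σ_i log f(o_i | damage) − log f(o_i | baseline)`
  over 5′ C-reference sites; reads scoring > 1 count as
  damage-supporting.
* −Δ% `= Σ max(0, n_i − n_{i+1}) / Σ |n_i − n_{i+1}|`; > 0.9 indicates
  the declining edit-distance histogram expected of authentic ancient
  assignments.
* Copy number: `CN_h = s · odds_h` with `odds = r/(1−r)` and
  `s = CN_anchor / mean(anchor odds)`, so the anchor group's mean
  estimate is exact.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (about a minute in total) and write tables under `results/`:

```bash
python analysis/01_simulate_study_data.py
python analysis/02_authenticate.py
python analysis/03_bdtt.py
python analysis/04_diet.py
python analysis/05_copynumber.py
```

`02_authenticate.py` prints:

```
bacterial screen: 56/56 taxa pass (reads > 500, PMDS>1 reads >= 50, -delta% > 0.9, C->T at 5')
dietary screen:   3/3 taxa pass (reads > 100, -delta% > 0.9, C->T at 5')
simulated reads: position-1 C->T 21.4%, fitted decay p0=0.206, lam=0.414
synthetic taxon summary: 20000 reads, 2923 with score > 1, -delta% 1.00 -> PASS
```

— every published Solarolo row passes its screening rule, and the
simulated reads (generated at p0 = 0.2, λ = 0.4) give back their damage
parameters to ~3%. `03_bdtt.py` shows the planted scale disparity:

```
BDTT Mantel R^2 by slice age (envelope upper bound in brackets):
  phylogeny  0: 0.58 [0.19]  100: 0.55 [0.19]  300: 0.47 [0.17]  500: 0.37 [0.19]  700: 0.38 [0.16]  900: 0.10 [0.11]
  ecology    0: 0.06 [0.06]  100: 0.06 [0.06]  300: 0.17 [0.08]  500: 0.15 [0.06]  700: 0.05 [0.07]  900: 0.21 [0.12]
```

— the phylogeny correlation is strongest at young slices and decays with
age, while the ecology correlation emerges at the deep slices where the
group-structured clades live. `05_copynumber.py` recovers the planted
copy numbers (wolves 2, dogs 8, ancient 2) with the wolf anchor mean
exactly 2.

The same stages are available behind one CLI with a single config file:

```bash
coproscope run --seed 5 --outdir out/       # or --config pipeline.yaml
```

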