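# Methods

## Model and procedure

The package addresses two-class discrimination in a paired-tissue expression
design: each patient contributes a tumor profile and an adjacent-tissue
profile on the same probe set, concatenated into one feature vector per
patient with `tumor:`/`adjacent:` tags.  This is the single orientation flip
in the pipeline — matrices are stored probes × samples and analysed
patients × features.

**Monte-Carlo feature selection.**  For each of `s` draws of `m` features
(without replacement), `t` CART trees are grown, each on its own
class-stratified train/test split (`train_fraction`, default 0.66; every
class keeps at least two training samples and, where possible, one test
sample).  Trees use the information-gain criterion (entropies in bits),
are grown to purity with minimum leaf size 2 and no pruning — deeper trees
contribute more nodes and a smoother importance profile.  Each internal node
splitting on feature g adds `IG · (n_node/n_tree)^v` to g's per-tree sum,
which is weighted by the tree's held-out weighted accuracy to the power `u`.
Weighted accuracy is the mean per-class recall of the test confusion matrix;
classes with zero test-row total are dropped from the average (this avoids
0/0 and only affects very small test splits).  If a tree's test split is
empty (possible only when a class has exactly two members), the training
confusion matrix is used instead.

**Incremental feature selection.**  The ranking is computed once on the full
data set and reused inside LOOCV.  This mirrors the reference protocol but
induces feature-selection bias — the held-out sample has influenced the
ranking — so the curve's accuracies are optimistic for out-of-sample
performance.  The final set is the smallest k whose LOOCV accuracy is within
`delta` of the curve's maximum; `delta = 0.02` encodes the trade-off of
accepting 0.94 at 26 features over 0.96 at 175.

**Classifiers.**  The SVM uses an RBF kernel, cost 1, gamma = 1/d, and
per-training-fold standardization (matching the common R defaults of the
`e1071::svm` family of tools); comparators are CART, 1-nearest-neighbor,
Gaussian naive Bayes, and a majority-class baseline whose LOOCV accuracy
equals the majority prior exactly (a useful calibration check: leaving out a
majority sample keeps the majority, leaving out a minority one too).

**Filter bank.**  The four contingency-based scorers share a supervised
Fayyad–Irani MDL discretization (a binary split is accepted iff its gain
exceeds `(log2(n−1) + log2(3^k−2) − kE + k1E1 + k2E2)/n`, recursively;
constant or uninformative features collapse to one bin).  OneR merges
adjacent bins left-to-right until every bucket holds ≥ 6 samples (a trailing
small bucket merges backwards) and scores the majority-rule accuracy.
ReliefF uses every sample as an anchor, k = 10 nearest hits/misses under
Manhattan distance on range-normalized features, per-feature differences
normalized by range, miss classes weighted by prior odds; classes smaller
than k+1 contribute with their reduced neighbor count.  These parameter
choices follow the Weka defaults for the corresponding attribute evaluators,
which is how such comparisons are conventionally run; exact Weka
bit-compatibility (its sampling and fold policies) is not attempted.
Undefined ratios (zero feature entropy) score 0 so every ranking is total.

**Overlap statistics.**  The pairwise hypergeometric upper tail is computed
in log space as a suffix log-sum-exp of the log-pmf (accurate to ~1e−13
relative even for p ≈ 1e−60); P(x ≥ 0) is set to exactly 1.  Fold enrichment
is observed/expected overlap.  The universe defaults to the combined feature
count.  The multi-set (> 2 lists) exact intersection distribution is out of
scope; only pairwise tests are reported.

## Synthetic cohorts

The generator emulates a paired-tissue microarray cohort: Gaussian
log-intensities with per-probe baseline 8.0 ± 1.0 (arbitrary for rank-based
stages), residual SD `sigma` (default 1.0), and planted probes whose mean is
shifted by `effect·sigma` in phenotype-positive patients only (location
shift, no variance effect — the structure mean-difference rankers assume).
Planted probes within a tissue share equicorrelated noise via a latent
factor, `x = √ρ·z_common + √(1−ρ)·z_private`, with ρ = 0.3 by default — a
modest co-expression level typical of a co-regulated gene set; ρ is exact by
construction.  Defaults follow the reference design: 28 positive / 22
negative patients, 15 tumor + 11 adjacent planted probes, effect 2.0.
Probes-per-tissue defaults to 1,000 (a desk-scale stand-in for the ~25,000
probes of a full array).

What the generator does **not** model: batch effects, missing values,
intensity-dependent variance, lncRNA/mRNA probe classes, or correlation
among non-planted probes.  Passing tests therefore demonstrate that the
machinery recovers a known mean-shift signal under idealized noise, not that
it would rank real array data identically.

## Numerical and design choices

- `s, t, m, u, v` and the split policy are not fixed by the method's
  published uses; defaults are s = 1000, t = 5, m = ⌈0.05·d⌉,
  u = v = 1, train_fraction = 0.66, all exposed in `MCFSConfig`.  Raw RI
  sums are reported (no cross-tree normalization) — the ranking is invariant
  to any monotone rescaling anyway.
- Entropy base: bits everywhere.  The base cancels in rankings but pins test
  expectations.
- Tie-breaks: filter rankings break score ties lexicographically on feature
  ID.  The MCFS ranking instead breaks RI ties by a permutation derived from
  the run seed: with subsampled ensembles a sizeable block of features ends
  at exactly RI = 0, and a fixed alphabetic order inside that block would
  give a signal-free feature a deterministic (hence biased) rank; the seeded
  permutation keeps runs reproducible while leaving tied features
  exchangeable, so a null feature's rank is uniform across seeds.
- Degenerate inputs: pure training labels or all-constant features yield a
  leaf-only tree (empty node list, majority-class accuracy); a LOOCV
  training fold that loses a class predicts the remaining class and is
  counted normally; constant features score 0 for correlation and ReliefF
  and collapse to one bin under MDL.
- Determinism: every stage is a pure function of (inputs, config, seed); the
  pipeline derives per-stage seeds by hashing the stage name, and rerunning
  with the same seed is byte-identical (floats are written with shortest
  round-trip `repr`).
- Parallelism is not used; at the problem sizes the package targets, a
  single-threaded run of the full pipeline takes seconds to minutes.

## Problem sizes used by the test suite and acceptance script

Unit and property tests run on cohorts of 40–150 probes per tissue.  The
acceptance checks and `scripts/acceptance.py` use the reference design at
1,000 probes per tissue (2,000 combined features), MCFS with s = 200, t = 5,
and an IFS scan depth of K = 100 — deep enough to cover the key-set sizes
the delta rule can select at this signal strength, while keeping a full run
under half a minute.

## Known limitations

- The IFS protocol's reuse of a full-data ranking inside LOOCV (kept for
  fidelity to the reference workflow) inflates accuracies; an unbiased
  estimate would re-rank within every fold.  Related: when the planted
  per-feature effect is strong, the top-ranked features are individually
  near-perfect classifiers (winner's curse on top of a true effect of 2 SDs),
  the IFS curve saturates within a few features, and the delta rule selects
  a far smaller set than the number of planted features.  Recovering the
  full planted set through the selected key set alone should not be expected
  in that regime — the full MCFS ranking, which does recover it, is the
  appropriate readout.
- Weighted accuracy supports c > 2 classes, but the generator, classifiers
  and tests exercise the binary case only.
- The interdependency-graph extension of Monte-Carlo feature selection is
  not implemented.
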