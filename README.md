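# mcifs

Monte-Carlo feature selection and incremental feature selection for paired
tumor/adjacent expression cohorts.

## The problem

Given log-expression profiles of tumor tissue *and* the adjacent tissue for
each patient in a two-class cohort (here: pancreatic ductal adenocarcinoma
patients with or without perineural invasion, 28 vs 22), which of the tens of
thousands of probe-level features — from either tissue — best discriminate
the two groups?  With d ≈ 50,000 features and n = 50 patients, any direct
classifier overfits; the pipeline implemented here ranks features first and
only then builds a compact predictor:

1. **Monte-Carlo feature selection (MCFS).**  Draw *m* features at random
   (m ≪ d), grow *t* decision trees on stratified train/test splits, repeat
   *s* times.  Each feature *g* accumulates relative importance

   RI_g = Σ_τ (wAcc_τ)^u · Σ_{nodes n_g(τ)} IG(n_g(τ)) · (no. in n_g(τ) / no. in τ)^v,

   where wAcc is the tree's weighted accuracy (mean per-class recall) on its
   held-out split, wAcc = (1/c) Σ_i n_ii / Σ_j n_ij, and IG is the split
   node's information gain in bits.  Features are ranked F = [f₁, f₂, …, f_N]
   by RI descending.
2. **Incremental feature selection (IFS).**  For k = 1…K evaluate the top-k
   feature set with a classifier (RBF-SVM by default; CART, 1-NN, Gaussian
   naive Bayes and a majority-class baseline are available) under
   leave-one-out cross-validation, then pick the smallest k whose accuracy is
   within δ of the curve's maximum (complexity/performance trade-off).
3. **Comparators and overlap.**  Seven classical filter rankers (chi-squared,
   correlation, gain ratio, information gain, OneR, ReliefF, symmetrical
   uncertainty) are implemented natively; agreement between top lists is
   quantified with the exact upper-tail hypergeometric test
   p = Σ_{j≥x} C(a,j)·C(N−a,b−j)/C(N,b) and fold enrichment x/(ab/N).

A seeded synthetic-cohort generator plants discriminative probes
(15 tumor + 11 adjacent by default, standardized shift `effect·σ` in the
positive class, equicorrelated within a tissue) so the whole pipeline is
testable end to end without any external download.

## Worked example

```python
from mcifs import synthetic, io, model, mcfs

tumor, adjacent, ann, truth = synthetic.generate_cohort(
    synthetic.SyntheticSpec(seed=1))          # 28+22 patients, 1000 probes/tissue
data = io.combine_tissues(tumor, adjacent, ann)   # 50 patients x 2000 features
res = model.MonteCarloFS(data, mcfs.MCFSConfig(s=200, t=5, seed=2)).fit()
print(res.summary(top=5))
```

```
Monte-Carlo feature selection
  features: 2000   patients: 50
  trees: s=200 x t=5   m=100   u=1.0 v=1.0

 rank           feature_id   tissue        ri
    1    tumor:probe_00919    tumor 30.282975
    2    tumor:probe_00650    tumor 28.454217
    3 adjacent:probe_00922 adjacent 28.210802
    4 adjacent:probe_00696 adjacent 26.239209
    5 adjacent:probe_00213 adjacent 22.434924
```

Every top-ranked feature is a planted one (check against
`truth.feature_ids`), and the tissue tags attribute each to the block it was
planted in.  Continuing with the incremental scan:

```python
ifs_res = res.ifs(classifier="svm", k_max=100, delta=0.02)
print(ifs_res.summary())
```

```
Incremental feature selection (svm, LOOCV)
  peak accuracy 1.000 at k=3
  selected k=3 (accuracy 1.000, delta=0.02)
  tissue split: 2 tumor / 1 adjacent
```

At this planted effect size (2 residual SDs per probe) a handful of top
features already classifies perfectly under LOOCV, so the δ-rule stops at
k = 3; `ifs_res.plot()` draws the accuracy curve with the peak and selected
k marked.  On weaker, real-data-like signal the curve climbs gradually and
the selected set is correspondingly larger.

The same pipeline is scriptable from the shell:

```sh
mcifs run-all --outdir run1 --seed 7
```

writing `ranking.tsv`, `curve.tsv`, `key_features.tsv`, per-method filter
rankings, `comparison.tsv`, `enrichment.tsv` and a `manifest.json`; a rerun
with the same seed is byte-identical.

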