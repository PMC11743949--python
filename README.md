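# hginjury

Hypergraph-based analysis of injury patterns in elite women's water polo
under male-assisted training.

## The problem

When a national women's water-polo squad introduces **male-assisted female
training (MAFT)** — sparring against male partners to raise confrontational
intensity — the distribution of injuries across body sites shifts: joints
loaded in confrontation (shoulder, elbow-wrist, lumbar-sacral-hip) are hit
more often, stability joints used in treading and sliding (knee, ankle)
less. This package implements, end to end, an analysis of that shift for
sports-medicine researchers:

1. **Epidemiology** — per-site injury proportions under both training modes
   and two-tailed Fisher's exact comparisons (`hginjury.stats`).
2. **Hypergraph machinery** — athletes as vertices, training interactions as
   hyperedges; incidence matrices, KNN hypergraph construction,
   clique-expansion Laplacians `L = D_A − A` with
   `A_ij = Σ_e w_e h(i,e)h(j,e)/|e|`, and the smoothness functional
   `½ tr(XᵀLX)` (`hginjury.hypergraph`).
3. **Pattern extraction** — an HGNN encoder (node embedding
   `z_i = σ(Wᵀx_i + b)` plus hyperconvolution
   `σ(Σ_{e∋v} 1/|e| Σ_{u∈e} W h_u + b)`) trained jointly with an MLP head on
   the hyperedge reconstruction loss `Σ_j ‖a_j − p_j‖²`, followed by 2-D
   principal-component views and cluster-compactness statistics
   (`hginjury.hgnn`, `hginjury.pattern`).
4. **Classification** — the regularised hypergraph classifier **rHGNN**,
   minimising cross-entropy plus `½ tr(XᵀLX) + λ·Ω(X)` with
   `Ω(X) = α Σ_ij A_ij‖X_i−X_j‖² + β Σ_i ‖X_i‖²` (defaults λ=0.2, α=0.03,
   β=0.005), evaluated by repeated stratified cross-validation against its
   unregularised form and MLP / SVM baselines, plus the hyperparameter
   ablation grid (`hginjury.classifier`).

The study cohort (26 athletes observed under both modes) is confidential;
`hginjury.cohort` generates synthetic cohorts with the same structure —
26 athletes in the squad's 3/3/15/5 position split, 320-dimensional
standardised feature vectors, nine binary injury-site labels drawn at the
observed per-mode rates, and latent within-regime training groups that seed
hyperedges. Every stage is therefore testable without any data download.

## Worked example

The numbered scripts under `analysis/` run the full study; each writes its
table under `results/`.

```bash
python analysis/01_injury_epidemiology.py
```

```
site           traditional_count  maft_count  traditional_pct  maft_pct  p       significant
shoulder       9                  11          34.6             42.3      0.7761  False
elbow_wrist    2                  7           7.7              26.9      0.1400  False
knee           11                 6           42.3             23.1      0.2367  False
...
sites significant at alpha=0.05: 0/9
largest shift: elbow_wrist 7.7% -> 26.9% (p=0.140)
```

Shoulder injuries affect 34.6% of the squad under traditional training and
42.3% under MAFT; the elbow-wrist proportion more than triples. At n=26 per
mode no single site reaches p < 0.05 — the regime shift is directional, not
site-wise significant, which is exactly what Fisher's exact test should say
at this sample size.

```bash
python analysis/02_simulate_cohort.py 1
python analysis/03_pattern_analysis.py 1
```

```
trained 15 epochs (train loss 4.406 -> 2.971)
mean within-regime 2-D distance: maft=1.715 traditional=3.161 (maft tighter); silhouette=0.214
```

In the learned 2-D embedding the MAFT athletes form the tighter cluster
(mean within-group distance 1.7 vs 3.2), reproducing the qualitative
compactness contrast between regimes that motivates the pattern analysis.

```bash
python analysis/04_classification.py 1
```

```
method            acc            ppv            npv            sen           spec
 rhgnn 0.85600±0.0446 0.55227±0.3137 0.86654±0.0610 0.10422±0.1535 0.96370±0.0497
  hgnn 0.79496±0.0677 0.29683±0.2138 0.87379±0.0663 0.32128±0.1842 0.85341±0.0774
   mlp 0.83230±0.0512 0.39699±0.2580 0.87126±0.0692 0.23878±0.2221 0.91170±0.0447
   svm 0.85170±0.0502 0.48333±0.3319 0.86022±0.0655 0.10550±0.1649 0.96600±0.0447

best mean accuracy: rhgnn (0.8560 over 5 seeds x 5 folds)
```

Graph regularisation lifts mean cross-validated accuracy by ~6 points over
the unregularised HGNN at the study's cohort size — the ordering the method
is designed to produce. (Absolute values depend on the synthetic cohort's
separability and are not comparable to any real-data benchmark.)
`analysis/05_ablation.py` runs the λ/α/β ablation grid.

A `hginjury` command-line tool exposes the same stages
(`simulate`, `build-hypergraph`, `train-pattern`, `classify`, `ablate`,
`stats`); see `hginjury --help`.

## Layout

```
src/hginjury/      library: cohort, hypergraph, hgnn, pattern, classifier,
                   stats, nn, io, cli
analysis/          numbered drivers reproducing each stage of the study
tests/             pytest suite (unit, property and end-to-end checks)
scripts/           acceptance script
docs/methods.md    models, assumptions, numerical choices, limitations
```
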