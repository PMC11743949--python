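# Methods

This note documents the models implemented in `hginjury`, the assumptions
behind them, the numerical choices that were genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Cohort epidemiology

Per-site injury proportions are counts over the number of athletes observed
under each training mode (26; the same squad before and after the
male-assisted programme). Percentages are rounded half-up to one decimal,
matching the squad report's formatting (9/26 → 34.6). The report's caption
describes proportions "of the total number of injuries", but the printed
percentages are arithmetic over the athlete denominator (9/26 = 34.6%); the
implementation follows the arithmetic and this note records the
discrepancy.

Mode comparisons use the two-tailed Fisher's exact test on
`[[injured, uninjured], [injured, uninjured]]` tables at α = 0.05, with the
probability-mass convention: p is the total probability of all tables with
the observed margins whose hypergeometric probability does not exceed the
observed one. Because every probability shares the denominator `C(N, c₁)`,
the implementation enumerates exact integer numerators (`math.comb`) and
compares ties exactly; float round-off cannot reclassify a near-tie. The
test suite checks this against `scipy.stats.fisher_exact` on every 2×2
table with margins ≤ 30 (164,175 tables, max |Δp| ≈ 4e-16). No
multiplicity correction is applied, matching the original analysis.

Confusion-matrix metrics (ACC, PPV, NPV, SEN, SPEC) with zero denominators
are reported as missing, never as 0, so macro averages over injury sites
are not silently biased toward pessimism.

## Hypergraph operators

A hypergraph `H(V, E, W)` is stored as an incidence matrix `h(v,e) ∈ {0,1}`
plus positive hyperedge weights. Degrees are `Dv(v) = Σ_e w_e h(v,e)` and
`De(e) = |e|`. Duplicate hyperedges are retained and counted with
multiplicity.

**Vertex-space Laplacian.** The smoothness functional must act on vertex
embeddings, so the package uses the clique-expansion form

    A_ij = Σ_e w_e h(i,e) h(j,e) / |e|   (i ≠ j, A_ii = 0),
    L    = D_A − A,

which is symmetric, positive semi-definite, has zero row sums, and reduces
to the ordinary weighted graph Laplacian when all hyperedges are pairs.
The `|E|×|E|` expression `diag(De) − HᵀWH` sometimes quoted for hypergraphs
is dimensionally unable to act on vertex embeddings (and the product itself
is impossible with a hyperedge-diagonal W); it is provided as a clearly
labelled audit constructor, `hyperedge_space_laplacian`, with the weights
applied symmetrically, and is not used by any pipeline.

`smoothness(X) = ½ tr(XᵀLX)` equals `¼ Σ_ij A_ij ‖X_i − X_j‖²`; property
tests verify this identity against a brute-force pairwise sum on random
hypergraphs.

**KNN construction.** One hyperedge per vertex: the vertex plus its k
nearest neighbours by Euclidean distance (k = 5 by default, sized for
n = 26 cohorts), distance ties broken by lower vertex index so builds are
bit-reproducible. All weights are 1: the interaction frequencies/intensities
that would justify non-unit weights have no defined functional form, so the
unweighted construction is the defensible default.

## HGNN layers

The node embedding layer is `z_i = σ(Wᵀx_i + b)`. The hyperconvolution
layer updates vertex v from its incident hyperedges only:

    out_v = σ( Σ_{e ∋ v} (1/|e|) Σ_{u∈e} W h_u + b ),

i.e. `σ(Q X W + 1bᵀ)` with `Q_vu = Σ_{e ∋ v,u} 1/|e|`. Summing over *all*
hyperedges instead would give every vertex an identical update, so the
incident-only reading is the one implemented. A vertex in no hyperedge
receives `σ(b)` and a logged warning. Q is left unnormalised, which
matters for optimisation (below). Parameters initialise Glorot-uniform from
an explicit seeded generator; there is no global random state anywhere in
the package.

All networks are small (n ≤ a few hundred vertices, widths ≤ 64), so layers
are plain numpy arrays with hand-derived backward passes, validated in
development against central finite differences (relative error ≤ 3e-6) and
kept honest by the oracle-equivalence tests.

## Synthetic cohorts

The generator emulates the structure the analysis needs, not physiology:

* **Size and composition**: 26 athletes — 3 centers, 3 defensive centers,
  15 perimeter players, 5 goalkeepers — split 13/13 between regimes;
  D = 320 standardised features.
* **Labels**: nine binary injury sites per athlete (multi-label: the
  observed proportions sum to well over 100%), drawn independently per site
  at the observed per-mode rates (e.g. shoulder 9/26 traditional, 11/26
  MAFT) unless overridden.
* **Features**: isotropic Gaussian noise (σ = 1) plus, for each positive
  site label, an offset of `class_separation · noise_sd` (default 1.5)
  along a site-specific random unit direction. Class-conditional Gaussians
  are the minimal structure under which parameter recovery is well posed.
* **Regime compactness**: MAFT athletes' noise is scaled by
  `1/regime_compactness_ratio` (default 2), planting the tighter-MAFT-cluster
  contrast the pattern pipeline is meant to detect.
* **Interaction groups**: sampled within regime only (the programme changes
  sparring composition), sizes uniform on 3–6. Each regime is first
  partitioned into covering groups, then overlapping groups are added to
  roughly two memberships per athlete: every athlete trains in at least one
  group, as in a real squad, and no vertex is isolated by construction.

What passing tests on these cohorts show: the pipeline recovers planted
signal, respects chance when there is none, and detects planted compactness
and regularisation benefit at the study's scale. What they cannot show:
anything about real athletes — features are abstract scores with no HRV or
load dynamics, sites are independent given the regime, and group structure
is uniform rather than positional.

## Pattern pipeline

The encoder is a dense node-embedding layer (320 → 64, ReLU) followed by
**one** hyperconvolution (64 → 32, identity). With small interaction groups,
stacking two propagation rounds averages away most within-regime dispersion
— the very signal the 2-D visualisation is meant to display — so the single
propagation round is the default; the stack depth is configurable.

Hyperedge embeddings are member means (`a_j`); a 64/32 ReLU MLP with a
sigmoid output head reproduces them (`p_j`), and both models are trained
jointly on `Σ_j ‖a_j − p_j‖²` with Adam at 0.001. Because the sigmoid head
is bounded, targets are min-max scaled to (0,1) per embedding dimension
using the training hyperedges' ranges, recomputed each epoch and treated as
constants within a step. 20% of hyperedges (seeded) form a validation set;
training stops after 100 epochs or 10 epochs without validation
improvement, and the best-validation parameters are restored.

2-D views use full-SVD principal components — deterministic up to
scikit-learn's sign convention — rather than stochastic neighbour methods,
so tests can assert on coordinates. Compactness is quantified by mean
within-group pairwise distance and mean silhouette (samples in singleton
groups excluded, reported as missing). Hypergraph structure is summarised
by isolated-vertex count, mean pairwise hyperedge overlap and
clique-expansion component count.

## Regularised classifier (rHGNN)

Architecture: KNN hypergraph over all athletes' features, two
hyperconvolution layers (D → 64 ReLU → 32 identity) producing embeddings X,
and a linear head to per-site logits. Training is transductive
semi-supervised node classification: the graph spans all athletes (features
only — no label leakage), the loss sees only training-fold labels, and
held-out athletes are scored from the same forward pass.

The objective is

    J = CE(logits, y) + c(X) · [ ½ tr(XᵀLX) + λ·Ω(X) ],
    Ω(X) = α Σ_ij A_ij‖X_i−X_j‖² + β Σ_i ‖X_i‖²,

with defaults λ = 0.2, α = 0.03, β = 0.005. CE is the mean binary
cross-entropy over labelled (athlete, site) entries; sites single-class in
the training fold are skipped with a warning. The smoothness weight matrix
is the clique-expansion adjacency A — the off-diagonal entries of L itself
are non-positive, which would make the "smoothness" term reward roughness,
so A is the only non-negative reading consistent with the term's purpose.

**Penalty normalisation** was the central open numerical choice. The raw
quadratic forms scale with `n · d · mean(X²) · mean-degree`, so with any
fixed coefficient they either dwarf the per-sample cross-entropy (the
embeddings collapse toward constants and accuracy drops to the majority
rate) or vanish. The package multiplies the penalty block by

    c(X) = 1 / ( n^{3/2} · d · mean(X²) · mean_degree(A) ),

with `mean(X²)` a stop-gradient constant per step. Dividing by
`n · d · mean(X²) · mean_degree` turns the penalty into a scale-free
*relative roughness* of the embedding cloud (magnitude control is left to
the β term); the extra `1/√n` makes regularisation strength decay relative
to the per-sample loss as cohorts grow, the usual behaviour of a prior.
Under this scaling the same defaults deliver both desiderata: ~0.92
held-out accuracy on well-separated n = 200 cohorts, and a consistent
accuracy gain over the unregularised model at n = 26.

**Optimisation**: full-batch SGD, learning rate 0.01 with momentum 0.9,
halved every 150 epochs, 400 epochs; the head is zero-initialised (logits
start at chance instead of saturated — the unnormalised Q otherwise
amplifies initial activations into the sigmoid tails), and gradients are
clipped to global norm 5 for the same reason. All choices are configurable.

**Evaluation**: repeated stratified k-fold (stratified on total injury
burden; folds re-drawn, with a log message, if a fold leaves no usable
site). Per-site one-vs-rest confusions on the held-out athletes are
macro-averaged with undefined metrics skipped; tables report mean ± std
across folds × repeats. Baselines: scikit-learn's MLP (64, 32, ReLU) and
per-site RBF-kernel SVMs; "hgnn" denotes the same architecture with every
penalty removed. The ablation grid evaluates the full model plus nine
single-parameter variations (λ ∈ {0.01, 0.1, 1}, α ∈ {0.001, 0.01, 0.1},
β ∈ {0.0001, 0.001, 0.01}) in a fixed row order.

## Problem sizes and determinism

Simulation-based checks use the sizes the analyses are designed around:
n = 200 cohorts for signal recovery and chance calibration, 25 seeds of
n = 26 cohorts (5-fold CV) for the regularisation-benefit sign test, and 20
seeded runs for the compactness direction. Every stochastic routine takes
one integer seed and threads it through a single `numpy` generator;
identical seeds give bit-identical cohorts, models and reports. The
acceptance script (`scripts/acceptance.py`) derives all child seeds from
its `--seed` argument.

## Known limitations

* Findings on synthetic cohorts quantify internal consistency, not clinical
  effects; absolute classification metrics depend on the planted
  separability.
* The per-site Fisher comparisons at n = 26 have low power; the pipeline
  reports directional shifts without claiming site-wise significance.
* The hyperedge-space Laplacian constructor exists only for audit; no
  pipeline result depends on it.
* Hyperedge weights are fixed at 1 throughout; weighted constructions are
  accepted by the data structures but no estimator for interaction
  intensity is provided.
* The MLP pattern head is trained purely for reconstruction; the package
  assigns no semantic meaning to individual pattern outputs.
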