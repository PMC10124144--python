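# Methods

## Classification model

Pixels are classified one-vs-all: one binary problem per tissue class,
positive pixels labelled +1, negatives −1, excluded pixels dropped. The
classifier is an additive logistic model over regression trees,

    f(x) = τ0 + ν · Σ_k τ_k(x),        p(x) = σ(f(x)),

whose raw output f is the log-odds of class membership. τ0 is the
training-set base-rate log-odds ln(n_pos/n_neg). Trees are fitted by
second-order (Newton) boosting on the logistic negative log-likelihood:
with current probability p_i and 0/1 target t_i, gradient g_i = p_i − t_i
and hessian h_i = p_i(1 − p_i); splits are found by exact greedy search
maximising the L2-penalised gain

    G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ),

and leaf values are −Σg/(Σh+λ). Rows are subsampled once per boosting
round and columns once per node, which decorrelates the trees; both are
driven by a single seeded generator, so training is bit-reproducible.

Tunable parameters (defaults in parentheses): number of trees K (100),
maximum depth (4), shrinkage ν (0.3), L2 leaf penalty λ (1.0), row
subsample (0.8), per-node column subsample (0.8), minimum rows per child
(5), decision threshold η on the probability (0.5, ties predicted
positive), positive-class fraction after negative downsampling (0.25),
held-out test fraction (0.25). ν and η and the ≈25 % positive share are
the workflow's standard operating points; K, depth, λ and the subsampling
rates are conventional gradient-boosting defaults and are all exposed in
`TrainingConfig` / `PipelineConfig`. Performance is reported with
imbalance-aware statistics — precision, recall, specificity and balanced
accuracy (mean of recall and specificity) — on a stratified hold-out
split; a rate with an empty denominator is reported as undefined rather
than coerced to a number.

## Observational Shapley attribution

The attribution target is the raw log-odds margin f, never the
probability: f is additive across trees, so the Shapley operator
distributes over the ensemble and per-tree attributions sum exactly.

For a coalition S of conditioned features, a tree's conditional
expectation E[τ(x)|S] is estimated tree-path-dependently: at a split on a
feature in S the observation's own branch is followed; at a split on a
feature outside S both children are averaged with weights proportional to
their covers. Cover is defined here as the number of *full training-set*
rows routed through the node, recomputed after each tree is grown — not
the per-round subsample — so the expectations reference the training
distribution the model was fitted to. This is the observational
formulation: credit is shared among statistically dependent features, which
is the appropriate behaviour when many m/z species participate in common
biochemistry. Interventional attributions are deliberately out of scope.

Three independent routes compute the same quantity:

- an ordering oracle — the literal average over all D! orderings of the
  tree's used features (capped at D ≤ 8);
- a subset oracle — the weighted sum over all 2^D coalitions with weights
  |S|!(D−|S|−1)!/D! (capped at D ≤ 15);
- the production path-dependent polynomial-time recursion, which
  maintains per root-to-leaf path the weighted number of feature subsets
  of each cardinality via extend/unwind updates.

The caps keep the oracle suites at sub-second cost; features absent from a
tree's splits receive exactly zero (the game collapses to the D used
features). The test suite sweeps hundreds of random trees (random
structure, thresholds, covers, repeated features along a path) and holds
the three routes to 1e-9 (path vs subsets) and 1e-12 (subsets vs
orderings); observed deviations are at machine precision. Local accuracy —
base value plus attributions reconstructs each pixel's margin — is
enforced at 1e-6 and observed at ~1e-14. Consistency (monotonicity) is
inherited from exactness of the Shapley computation and is not separately
tested.

Global scores Φ_j = mean_i |φ_ij| are averaged over **all** pixels of the
sample by default (explanation needs no labels); a `labeled_only` scope
restricts to annotated pixels. Ranking is by descending Φ with ties broken
by ascending m/z so the order is total and reproducible.

## Routing and numerical conventions

- Split routing is `x[j] <= threshold` → left child, equality left, and
  the *same* shared convention is used in training, prediction and the
  Shapley traversals; mixing conventions would silently break local
  accuracy.
- Trained split thresholds are set to the left child's maximum observed
  value, so `<=` reproduces the sorted partition exactly with no midpoint
  rounding concerns.
- Imported xgboost boosters route `x < t` to the yes-branch; thresholds
  are converted to `nextafter(t, −inf)`, making `x <= t'` bitwise
  equivalent to `x < t` for every float. Imported leaf values already
  include shrinkage, so imported ensembles use ν = 1. Agreement with the
  external booster is bounded by the float32 precision of its dumps and
  outputs (observed ≲ 1e-6 on margins, ≲ 5e-7 elementwise on
  attributions; the cross-check tolerance is 1e-4).
- Gain comparisons use a 1e-12 slack so exactly-tied splits resolve to the
  first candidate in column order, deterministically.
- A degenerate rate (empty class) is `None`; an all-zero SHAP map renders
  with colour limits ±1; direction calls with fewer than 10 pixels or a
  constant input are INDETERMINATE with statistic 0.

## Direction calls

The correlative/anticorrelative judgement — does high intensity coincide
with positive attribution? — is a visual one in practice; it is
operationalised as the Spearman rank correlation between a feature's
intensity and its Shapley value over the evaluated pixels, with verdicts
CORRELATIVE above +0.3, ANTICORRELATIVE below −0.3, INDETERMINATE
otherwise. Rank correlation is used because intensities are log-normal and
the attribution–intensity relation is monotone but not linear; the
threshold is config-exposed.

## Phantom generator

The phantom emulates the structure of annotated tissue-section IMS data:

    X[i,j] = exp( μ + δ[i,j] + σ·Z[i,j] )

with baseline log-mean μ (default 1.0), multiplicative log-normal noise of
scale σ (default 0.3 — ion counts are multiplicative), planted region
effects δ (UP markers +effect, DOWN markers −effect inside their region,
on the natural-log scale), optional correlated noise pairs (shared latent
Gaussian with configured ρ), and an optional artifact that adds a fraction
of a marker's effect into a bleed region outside its home region —
emulating analyte-delocalization confounds. Region masks label the region
POS, other regions NEG, and a 1-pixel ring along region boundaries
EXCLUDED, mirroring the practice of excluding hard-to-annotate border
pixels; ring width 1 is a default, not a claim about any particular
annotation protocol.

The canonical demo phantom is a 32×32 grid, 50 features, an elliptical
target inside a background region, five planted target markers (three UP,
two DOWN) and one correlated non-marker pair. Marker effects span 0.6–1.0
log units (≈1.8–2.7× fold changes): individually informative at σ = 0.3
but only jointly separating, so the classifier must combine them — the
regime the attribution method exists for. (With markers several times
stronger, a boosted ensemble legitimately ignores redundant weak markers,
which is a property of boosting, not an error; such phantoms make poor
recovery benchmarks.) The artifact variant bleeds 80 % of one UP marker's
effect into an ellipse in the background, which reproduces the
qualitative confound signature: positive mean attribution of the bled
marker inside the bleed region, negative for clean markers.

What the phantom does **not** emulate: isotope envelopes, mass-axis
jitter, spatial intensity gradients, pixel-to-pixel spatial correlation of
noise, matrix/suppression effects, or realistic peak-picking artefacts.
Passing tests therefore demonstrate correctness of the workflow's
computations and its behaviour under planted ground truth — not
performance claims about any real tissue dataset.

## Pipeline

A master seed is expanded into stage seeds (negative downsampling,
hold-out split, training) through numpy's `SeedSequence`, so each stage is
individually reproducible and all artifacts (ranking CSV, metrics JSON)
are byte-identical across reruns. The pipeline withholds the marker
ranking when held-out balanced accuracy is below a configurable floor
(default 0.8), writing a warning artifact instead — explanations of a
weak classifier are not marker evidence. Problem sizes used throughout the
test and acceptance suites: 1,024-pixel phantoms, 50 features, 100-tree
depth-4 ensembles, ten independent seeds; these run in roughly two minutes
on one CPU.

## Known limitations

- Exact greedy split search is O(m·n) per node and is intended for
  peak-picked matrices (hundreds to a few thousand features), not
  profile-mode spectra; histogram-based splitting is out of scope.
- The explanation cost is O(pixels · trees · leaves · depth²); explaining
  very large samples (10^5+ pixels) is better done on a pixel subset or
  the labeled scope.
- Direction calls summarise a feature's *global* monotone association;
  spatially heterogeneous relationships (the very thing SHAP maps reveal)
  can be INDETERMINATE globally while clearly structured locally —
  region-level reading of the maps remains the user's task.
- Multiclass problems are handled strictly one-vs-all; no softmax
  objective or composite multi-class maps.
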