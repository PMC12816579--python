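# Methods

This note documents the models, the synthetic benchmark, the numerical
conventions, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and units

A chemical record carries a raw SMILES, an optional standardized SMILES,
per-endpoint PODs in mg/kg-d with the number of underlying experimental
data points (`n_support`), and optional ClassyFire-style taxonomy labels.
Records whose POD rests on fewer than 4 data points are filtered out by
default: surrogate PODs derived from few observations carry high aleatoric
uncertainty. Models work internally in log10(mol/kg-d) —
log10((POD/1000)/MW) — the scale on which dose relates to molar activity;
presentation output is back-converted to mg/kg-d. PODs for dioxin-like
compounds can be derived from an index compound via toxic equivalency
factors as POD_index / TEF: TEF is a relative potency, so a more potent
congener (TEF > 1) gets a lower POD. The division convention is this
package's choice; it follows directly from the definition of relative
potency.

## Structure standardization

Simplified, deterministic rule set (not a full published standardization
workflow — no tautomer canonicalization or valence correction):

1. unparseable SMILES → excluded (`unparseable`);
2. no carbon in any component → `inorganic`;
3. keep the largest organic component (most heavy atoms; ties broken by
   molecular weight, then canonical-SMILES order — deterministic salt and
   solvent stripping);
4. any atom outside {H,B,C,N,O,F,Si,P,S,Cl,Se,Br,I} in the retained
   component → `organometallic`;
5. retained component > 1000 g/mol → `too_large`;
6. otherwise the canonical SMILES of the retained component.

Exclusions are returned, not raised, so the "expanded" training mode can
retain non-standardized chemicals. Charged fragments are kept as-is (no
neutralization); canonicalization makes the operation idempotent.

## Descriptors and leakage-free preprocessing

Four families: MACCS keys (166 bits), Morgan fingerprints (default 1024
bits, radius 2), RDKit 2-D physicochemical descriptors, and precomputed
learned embeddings ingested from a table (they require a pretrained
network, which is out of scope). Knowledge-based families (MACCS,
physchem) are correlation-filtered: features are scanned in input order and
a feature is dropped when |Pearson r| > 0.9 against an already-kept feature
— the threshold is the substantive choice, the in-order greedy tie-break
just makes it deterministic. Pearson on 0/1 MACCS columns is used exactly
as for continuous columns. The physchem block additionally gets a
Yeo-Johnson transform and zero-mean/unit-variance scaling; zero-variance
columns are dropped (scaling is undefined there). Structural
representations (Morgan, embeddings) pass through untouched — their bits
are only a valid representation jointly. All parameters are fitted on
training rows only; `apply` never refits. The leakage contract is tested by
hashing fitted pipelines under test-fold corruption.

## Quantile regression forest

Trees come from a standard random-forest regressor (bootstrap, default 500
trees, minimum leaf size 5, all features considered per split by default —
settings exposed in config; they are conventional forest defaults, not
tuned values). Leaves are defined over *all* training points routed through
the fitted tree, so the Meinshausen weight of training point i at query x —
the tree-average of 1[same leaf]/leaf-size — is deterministic given the
forest and checkable by brute force; the test suite asserts exact equality
against an independent brute-force weighted-CDF oracle on small instances.
Quantiles use the left-continuous inverse CDF, inf{y : F̂(y) ≥ q},
everywhere (per tree and for the ensemble), so estimates are nondecreasing
in the level and order statistics are reproducible bit-for-bit.

## Uncertainty-aware conformalization

Nonconformity scores divide the raw quantile residuals by the per-query
epistemic spread s(x) = SD of per-tree median predictions, floored at 1e-6
to protect pure leaves. The adjustment ĉ is the ⌈level·(n_cal+1)⌉-th
smallest calibration score (capped at n_cal), giving the standard
split-conformal marginal coverage guarantee; s ≡ 1 (plain CQR) is a config
option. Intervals at other confidence levels reuse the *stored* scores with
a level-dependent rank: the score function stays fixed and only the
conformal quantile moves, so the finite-sample guarantee holds at every
requested level — this is what the confidence-calibration curve (levels
1–99%) consumes. At low levels ĉ can be negative and the interval shrinks
inside the raw quantile pair; the median is clipped into the interval.
Final models for library screening are retrained on all data with an
internal stratified 20% calibration split (fixed seed).

A caution worth recording: the per-tree spread s(x) does *not* keep
growing with distance outside the training range in low dimensions — past
the data boundary every tree routes a query to its extreme leaf and the
spread saturates. The epistemic signal is real in higher-dimensional,
cluster-structured feature space (held-out clusters get visibly larger
spread and wider intervals), which is the regime the distance-based
calibration tests exercise.

## Bayesian neural network

Architecture: input → one hidden ReLU layer (default width 128; tests use
32 for speed) → two outputs, the predictive mean and, through a softplus
link (floored at 1e-4), the predictive SD — so aleatoric noise is modeled
per input. Each weight has an independent Gaussian variational posterior
(σ = softplus(ρ)); the prior is a scale mixture of two zero-mean normals
(defaults π = 0.5, σ1 = 1.0, σ2 = 0.0025 — a soft spike-and-slab). The
loss is a Monte-Carlo negative ELBO using the same reparameterized weight
samples for the KL and likelihood terms (the mixture KL has no closed
form). Gradients are analytic: with Gaussian q the direct ∂log q/∂μ term
cancels against the pathwise one, and the ρ-gradient collapses to
(g_w·ε − 1/σ)·sigmoid(ρ), where g_w is the gradient of the data and prior
terms with respect to the sampled weight. The implementation is NumPy
end-to-end with Adam and is deterministic given the seed. Optimizer, width,
epochs and prior settings are config-exposed; the architecture family is
fixed, its hyperparameters are not asserted anywhere.

Predictions are Monte Carlo (default 500 draws: weights from q, then the
Gaussian output), summarized by percentiles with linear interpolation
between order statistics — pinned so summary tests are bit-stable. The
reported per-chemical predictive SD is the SD of the draws.

## Calibration diagnostics

*Confidence-based*: observed coverage at integer levels 1–99%;
ECE = mean |level − observed|. For the BNN, levels are central percentile
intervals of the draws.

*Error-based*: items sorted by predictive SD (stable sort) into
B = round(√n) batches — sizes floor(n/B) with the remainder going one each
to the highest-uncertainty batches. Per batch, RMU = √(mean σ²) and
RMSE = √(mean squared error); ENCE = mean_b |RMU_b − RMSE_b|/RMU_b. The
half-up rounding of √n matters: at the curated dataset sizes n = 2357 and
n = 1845 it yields B = 49 and 43 with batch sizes 48–49 and 42–43
respectively (floor would give 48–50 and 43–44). Because ENCE is sensitive
to B, `ence_sensitivity` sweeps B = 5..200.

*Distance-based*: same batching; per batch the mean Jaccard distance
d(a,b) = 1 − |a∧b|/|a∨b| (empty-union pairs defined as distance 0) to the
k = 5 nearest training Morgan fingerprints. For conformal intervals the
per-chemical σ is the Gaussian-equivalent width/(2·z_{0.975}) ≈ width/3.92;
for the BNN it is the SD of draws. These σ conventions are package choices:
some convention is needed to put asymmetric conformal intervals and
sampled posteriors on one RMU scale, and the Gaussian-equivalent form is
the least surprising.

## Cross-validation and model comparison

Repeated, target-stratified k-fold CV (default 10 outer folds): targets are
cut into quantile bins (default 10) and each bin is dealt round-robin to
folds after a seeded shuffle, so every fold spans the full potency range of
a heavy-tailed target. Feature preprocessing and the conformal calibration
split happen strictly inside each training fold. Conventional baselines
(linear, kNN, SVM, random forest, gradient boosting, MLP) are standard
scikit-learn estimators behind the same interface, with small default
grids searched over 5 inner folds when a grid is given. Metrics: MAE,
MdAE, RMSE, R² (and adjusted R² when the feature count is supplied), plus
Pearson/Spearman.

Paired comparisons support both printed conventions: classic per-unit
paired t (df = n−1) and per-repeat scores with the Nadeau–Bengio variance
correction (1/r + n_test/n_train, default ratio 1/9 for 10-fold CV,
df = repeats−1). The consensus baseline averages the best (lowest mean
score) model with every model not significantly worse than it at α = 0.05
under the corrected test; the stricter include-only-significantly-best
reading is available behind a flag because the inclusion rule is genuinely
ambiguous.

## Synthetic benchmark

`make_synthetic_qsar` generates what the calibration machinery needs and no
more: cluster prototype bit-vectors (P(bit) = 0.1 over 1024 bits) with
per-member seeded bit flips (default rate 0.05) give binary fingerprints
with controlled within/between-cluster Jaccard distances; 5 latent
continuous descriptors (cluster centers N(0, 2²) plus within-cluster
N(0, 0.6²) noise) carry the signal; the target is a per-cluster offset plus
a linear descriptor term, rescaled so signal variance + mean noise variance
hits `target_variance_goal` (0.69 emulates the rd-like regime, 1.17 the
nc-like one); the noise SD is affine in the standardized first
within-cluster coordinate (0.2 + 0.3|u|), giving the heteroscedasticity
the interval models must capture. Ground-truth signal and σ are returned
for oracle tests. What it does *not* emulate: real chemistry (activity
cliffs, scaffold hops, descriptor redundancy structure), measurement-error
correlation across endpoints, or class imbalance in taxonomy — so passing
tests demonstrate the statistical machinery, not performance on real POD
data. The toy fixture (~25 real SMILES with fabricated PODs and support
counts) covers the RDKit featurization and every standardization branch.

The standard coverage benchmark uses n_train = 1000, n_cal = 500,
n_test = 2000 — large enough for stable coverage estimates and small enough
that the whole suite runs in minutes on one CPU; multi-seed assertions use
10–20 seeds on the same reasoning.

## Known limitations

- No 3-D, conformer or stereochemistry-aware features; enantiomers are
  indistinguishable to every descriptor family shipped.
- The BNN is deliberately small-scale; no architecture search or deep
  ensembles. Its calibration tends toward underconfidence (overestimated
  uncertainty) rather than the reverse.
- Learned embeddings are ingest-only; the package never computes them.
- The calibration suite diagnoses miscalibration but never rescales
  intervals.
- Non-standardized chemicals can be screened only by models trained on the
  expanded dataset, and such predictions are flagged provisional: their
  uncertainty is high and may still be underestimated.
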