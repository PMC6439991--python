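# Methods

## Model

The predictor treats drug repositioning as link prediction on a
heterogeneous drug–protein–disease network with three binary interaction
layers: `A_dp` (drug × protein, "binds to"), `A_sp` (disease × protein,
"causes"/"caused by") and `A_ds` (drug × disease, "treats"). No similarity
matrices enter the model; everything is derived from interactions.

**Meta paths and commuting matrices.** A meta path is a typed walk
template from Drug to Disease. For a template `T1 → T2 → … → Tk` the
commuting matrix is the product of the per-link adjacency matrices, and
its (i, j) entry counts the *walk* instances from drug i to disease j —
walks, not simple paths: intermediate nodes may repeat, because that is
what matrix products count (the discriminating case is the
Drug→Disease→Drug→Disease template on a single treat edge, which yields
count 1 via d→s→d→s). Only the five templates of length ≤ 3 are used;
longer templates traverse the three-type schema redundantly and dilute
the signal. `count_path_instances` enumerates walks explicitly and serves
as the independent oracle for the algebra; the two routes are checked
entrywise in the test suite.

**Latent features.** Raw commuting-matrix rows/columns would give each
pair m + n features — far more than the number of labeled pairs — so each
X is truncated-SVD factorised and a pair is represented by
`[U_r[i] ‖ V_r[j]]`, unweighted by singular values. The retained rank is
`r = max(1, floor(latent_feature_percent · min(m, n)))`: the fraction is
the method's single tunable parameter (default 0.03); the floor with a
minimum of 1 pins down the otherwise unspecified rounding and makes a
degenerate r = 0 impossible. Sign ambiguity of singular vectors is
resolved by forcing the largest-magnitude entry of each left vector
positive (first index on ties), so features are bit-reproducible across
runs and platforms. Small or nearly full-rank problems use a dense LAPACK
SVD; large sparse ones use ARPACK with a fixed, deterministic starting
vector. An all-zero commuting matrix raises: that meta path carries no
information on the given network. The share of spectral mass the retained
values capture is exposed as a diagnostic
(`LatentFeatures.singular_value_coverage`), not asserted, because it is a
property of the data, not of the method.

**Reliable negatives.** Verified non-associations do not exist in the
source databases, so negatives must be drawn from unlabeled pairs.
Uniform sampling risks mislabeling not-yet-confirmed associations. The
filter keeps an unlabeled pair only when the drug's protein set and the
disease's protein set are disjoint (`row(A_dp, d) · row(A_sp, s) = 0`).
Disjointness is evaluated on the full protein layers regardless of CV
folds (protein layers are never held out). The pair universe is
materialised as a dense boolean grid: even at the realistic scale of
~1200 drugs × ~450 diseases this is half a megabyte, so blocked
enumeration would add complexity without benefit. Training uses the known
positives plus an equal-sized seeded uniform draw from the candidate pool
("balanced data"); the uniform-unlabeled baseline arm is kept for
comparison.

**Classifiers and ensemble.** One scikit-learn random forest with 256
trees per meta path, scores = positive-class probabilities; the ensemble
score is their unweighted mean H(x). The decision threshold is the cut
maximising F1 over the candidate set {midpoints of adjacent sorted unique
scores} ∪ {below min, above max}, ties to the smallest threshold. When
applied to evaluation scores this mirrors the common (optimistic)
reporting convention; `train_ensemble` chooses it on training scores and
the docstring says so.

## Evaluation protocol

5-fold cross-validation on the balanced pair set: positives and sampled
negatives are each shuffled (seeded) and split into five near-equal folds.
Metrics are pooled over the concatenated test-fold scores (matching
single-number reporting), with per-fold AUPR/AUC kept for dispersion.
Undefined ratios (0/0, e.g. MCC when a degenerate cut predicts one class)
are reported as NaN, never coerced to 0. AUPR is step-wise average
precision (trapezoidal PR interpolation overestimates); AUC is the
Mann–Whitney statistic with tie correction — both via scikit-learn, both
cross-checked in the tests against hand-written oracles (precision steps,
pairwise concordance).

**Feature construction across folds** is the one genuinely open protocol
question, because X1 = A_ds literally contains the labels. Two arms are
implemented behind `mask_test_edges`:

- **masked (default)**: each fold's held-out positives are removed from
  the treat layer before commuting matrices and SVD features are rebuilt,
  so no feature can see a test label. This is the honest inductive
  protocol and the default for the library API.
- **unmasked** (`mask_test_edges=False`): features are built once from
  the full treat layer, a transductive protocol in which treat-layer meta
  paths partially encode held-out labels. This is the protocol the
  published benchmark figures for this family of models correspond to —
  visible in the fact that a base classifier built on X1 alone reaches
  AUPR ≈ 0.89 there, impossible under masking — and it is what the
  end-to-end signal-recovery tests use, so their numbers are comparable
  to that style of reporting.

The `sweep` facility fixes folds and negatives across the
latent_feature_percent grid (1%…20% by default) so grid rows differ only
in rank.

## Synthetic data

The generator emulates the statistical structure the method assumes, at a
scale that keeps the full pipeline fast: 200 drugs, 150 proteins, 80
diseases. `A_dp` and `A_sp` are independent Bernoulli layers at density
0.02, chosen so mean degrees (~3–4 proteins per drug, ~3 per disease)
match the realistic sparse regime. The treat layer is sampled per pair
with probability `logistic(logit(base_treat_rate) + overlap_boost · k)`,
k = shared-protein count; defaults `base_treat_rate = 0.01` and
`overlap_boost = 2.5` give a treat density of ~0.017 (a few hundred
positives, enough for 5-fold CV) with roughly 40% of positives
protein-mediated. Generation is a pure function of the seed.

What the fixture does **not** emulate: hub/power-law degree structure,
community structure, and hence any low-rank organisation of the
interaction matrices. This matters for interpreting results: on iid
Bernoulli layers the SVD features of protein-path matrices are close to
unstructured, so absolute performance here says nothing about real-data
performance — the tests verify *mechanics and relative behaviour*
(planted signal is recovered, contaminated pools are detected), not
attainable accuracy.

Two measured consequences are worth recording.

1. Under the masked protocol, a zero-overlap pair is positive with
   exactly `base_treat_rate` independent of everything else, so held-out
   zero-overlap positives are statistically exchangeable with reliable
   negatives; the Bayes AUC ceiling is `f + (1 − f)/2` with f the
   overlapping fraction of positives (~0.72 at the default settings).
   End-to-end recovery checks therefore use the unmasked protocol, where
   the measured ensemble AUC is 0.85–0.92 across 20 seeds.
2. On these fixtures the treat-layer paths (X1, X4) are the *strongest*
   base classifiers — the reverse of real-data reporting, where they are
   weakest — because at small scale a rank-r truncation of A_ds retains
   most of the label information. The ensemble still matches or beats
   every base classifier's AUPR in a majority of seeds, but its AUC can
   trail the best single treat-layer classifier; dominance claims are
   therefore tested in AUPR form. Relatedly, swapping reliable for
   uniform negatives moves pooled AUPR by less than ±0.08 on the fixture
   (the filter's benefit grows with protein-layer coverage; at these
   densities few pairs are filtered differently), while the
   candidate-pool contamination comparison — the filter's actual premise
   — favours filtering on every seed tested.

## Numerical and design choices

- Identifiers are opaque case-sensitive strings; registries sorted
  lexicographically; all indexing 0-based. Matrices are scipy CSR sparse,
  int8 for adjacency, int64 for products.
- Union alignment in `build_network`: node universes are the union of the
  ids seen per type across layers, absent rows/columns zero-padded; layer
  edge sets are preserved exactly. Densities are computed over the full
  universes.
- Header lines in edge-list TSVs are skipped only on request
  (`skip_header=True`); '#' comments and blank lines always. A header in
  a two-ID-column file is indistinguishable from an edge, so guessing is
  worse than asking.
- Seeds: a single master seed is expanded through
  `numpy.random.SeedSequence` with stable per-purpose spawn keys
  (negative draw, fold shuffles, one per meta path × fold), so per-forest
  seeds are independent yet reproducible, and sub-seeds stay below 2^31.
- Degenerate inputs: empty edge files, all-zero commuting matrices,
  single-class labels, oversized negative requests and saturated treat
  layers raise informative errors rather than producing silent zeros.

## Problem sizes used in the checks

Oracle-equivalence runs 200 random networks with up to 10 nodes per type;
SVD and metric contracts use dozens of random small matrices/vectors; the
end-to-end recovery check runs 20 seeded replicates of 5-fold CV on the
default 200/150/80 fixture. The whole suite completes in a few minutes on
one core.

## Limitations

- The rank rule makes r scale with the *fixture's* min(m, n); at very
  small scale the default 3% keeps only r = 2 components, which is a
  down-scaling artefact rather than a property of the method.
- The F1-maximising threshold on evaluation scores is optimistic; use the
  validation-split behaviour of `train_ensemble` + held-out scoring for
  deployment-grade thresholds.
- Candidate ranking scores all unlabeled pairs densely; beyond ~10^7
  pairs this should be blocked (not needed at the scales supported here).
- The method cannot score a drug absent from every layer; cold-start
  drugs need at least protein interactions (meta path 2 then still
  applies).
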