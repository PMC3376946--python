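# Methods

## Problem setting

An instance is a patient described by d binary symptom/sign indicators
x ∈ {0,1}^d and carrying a subset of Q binary diagnostic labels
(syndromes) Y ⊆ {1..Q}. Syndromes are not mutually exclusive and in
practice co-occur, which is what makes the task multilabel rather than a
collection of unrelated binary problems. The package's estimators consume
a `Dataset` — two row-aligned binary matrices with named columns — and
refuse non-binary or missing cells outright: the modelling assumes a fully
observed binary scale, and imputation is deliberately out of scope.

## The classifier

### ML-kNN core

For each label the model is a two-hypothesis Bayes rule over the count of
positive neighbours:

* prior `P(H1) = (s + Σ yᵢ) / (2s + n)` — the smoothed training
  prevalence;
* likelihoods `P(Eⱼ|H1)`, `P(Eⱼ|H0)` for j = 0..k, where Eⱼ is "exactly j
  of the k nearest neighbours carry the label". Estimated by counting
  leave-one-out neighbourhoods over the n training rows:
  `P(Eⱼ|H1) = (s + c₁[j]) / (s(k+1) + Σⱼ c₁[j])`, with c₁[j] the number of
  positive training instances whose leave-one-out neighbourhood contains
  exactly j positives (analogously c₀ for H0).

The posterior `P(H1|Eⱼ)` is the ranking score; prediction is score > 0.5,
which is the MAP decision over the two hypotheses. No threshold tuning is
performed.

Distances are exact Hamming distances on the binary vectors, computed as
|x| + |y| − 2·x·y via a single float64 matrix product (all intermediate
values are exact integers, so the distances are exact). For 0/1 data
Hamming ranking is identical to squared-Euclidean ranking. Neighbour ties
at equal distance break toward the lower training-row index, making every
fit and prediction fully deterministic. Neighbour search is brute force:
at the problem sizes this package targets (n ≈ 10³) a distance matrix is
cheap, and exactness is part of the contract (the test suite compares the
whole fit/predict path against a naive enumeration re-implementation).

### Label-specific subspaces (REAL)

Vanilla ML-kNN measures all labels in one shared space. REAL instead
gives label l its own input space: a filter selector ranks all d symptoms
against that label on the training split and keeps the top m; the label's
prior, likelihood tables, and all neighbour queries are computed in the
projected m-column matrix. Labels are otherwise treated independently —
no classifier chaining — and the per-label posteriors, which share the
[0,1] calibration, are used directly as the cross-label ranking scores.

With m = d every subspace is a column permutation of the full space;
Hamming distance is permutation-invariant, so REAL then reproduces
vanilla ML-kNN bit-for-bit. This degeneracy is the single most important
correctness check in the test suite.

### Filter selectors

All scorers use plug-in (unsmoothed) empirical probabilities, log base 2
(scores in bits), and the 0·log 0 = 0 convention:

* `mi` — I(X;Y) from the 2×2 contingency table;
* `ig` — H(Y) − H(Y|X). For discrete variables this equals MI; both are
  kept because each is computed along a different algebraic route, and
  their agreement to 1e-12 is asserted as a property test;
* `cmim` — greedy: first pick argmax I(X;Y), then each next pick
  maximises minₛ I(X_c; Y | X_s) over the already-selected s;
* `mrmr` — greedy MID form: each next pick maximises
  I(X_c;Y) − (1/|S|) Σₛ I(X_c;X_s).

Defaults are `ig` and m = 20. Every selector also reports the sign of
p̂(x=1|y=1) − p̂(x=1|y=0) per selected symptom, distinguishing positive
evidence ("specific" symptoms) from counter-evidence ("negative"
symptoms) without committing to either being selected preferentially.

**Tie handling.** Candidate scores within 1e-12 bits are treated as tied
and the lowest feature index wins. A hard equality test would make the
rule depend on floating-point summation order: two columns with permuted
contingency tables have mathematically equal scores that evaluate to
floats differing at ~1e-16.

## Evaluation measures

Given scores f(xᵢ,y), predictions and truth, ranks are computed per
instance with rank 1 = highest score and score ties broken toward the
lower label index (so all measures are deterministic under ties, and
invariant under any strictly monotone transform of a score row — both
property-tested):

* average precision — mean over true labels of the fraction of labels at
  or above their rank that are true;
* coverage — mean over instances of (max rank of a true label − 1),
  reported raw (range 0..Q−1) and normalised by Q;
* ranking loss — fraction of (true, false) pairs with f(true) ≤ f(false);
* hamming loss — fraction of misclassified instance–label pairs (all
  instances counted);
* one-error — fraction of instances whose argmax-score label is false;
* per-label accuracy — per-column agreement rate; mean(1 − accuracy)
  equals hamming loss by construction.

Instances with an empty truth set are skipped for average precision,
coverage and one-error; ranking loss additionally skips full truth sets.
Denominators shrink accordingly and the skip count is reported. If no
instance is evaluable the measure raises rather than returning a default.

## Synthetic data generator

The generator emulates the structural features such clinical datasets
exhibit, at their natural scale (defaults: n = 919 instances, d = 113
symptoms, Q = 6 syndromes):

* **Co-occurring labels.** Syndromes are sampled sequentially,
  z_l ~ Bernoulli(logistic(α_l + Σ_{j<l} w_{jl} z_j)); positive w makes
  syndromes co-occur. Defaults: base logits placing marginal prevalences
  in 0.1–0.4, coupling 0.7 between adjacent syndromes.
* **Specific and negative symptoms.** Each syndrome has 8 specific and 8
  negative symptoms (disjoint within a syndrome). A symptom with active
  specific parents fires by noisy-OR,
  p = 1 − (1−q_base)(1−β)^{#specific parents}, then active negative
  parents suppress it, p ← p(1−γ)^{#negative parents}. Defaults
  q_base = 0.15, β = 0.55, γ = 0.6. Probabilities stay strictly inside
  (0,1), and evidence is monotone: adding a specific parent never lowers a
  symptom's probability, adding a negative parent never raises it
  (property-tested).
* **Shared relevant pool + noise.** The six syndromes draw their sets
  from a common pool of 30 symptoms via a rotation (syndrome l takes pool
  slots 5l..5l+15 mod 30), so neighbouring syndromes share symptoms and a
  symptom can be specific for one syndrome and negative for another —
  both patterns real inquiry scales show. The remaining 83 symptoms are
  background-rate noise, which is what gives label-specific selection its
  advantage over a shared space.

What the generator does **not** emulate: ordinal/graded symptom severity,
rater disagreement and scale drift, missing answers, and any calibration
of marginal frequencies to a particular clinical population. Passing
tests on this generator therefore demonstrate structural correctness of
the algorithms (recovery of planted signal, the direction of REAL's
advantage, the interior peak of the feature-count sweep), not clinical
performance levels on real patients.

## Cross-validation protocol

k-fold CV (default 10 folds) with seeded balanced folds: a random
permutation followed by round-robin assignment, so fold sizes differ by
at most one. Feature selection runs inside each training fold — the
held-out fold never influences subspace choice. Reports are mean ± std
(ddof = 1) across folds for every measure plus per-label accuracy.
Model comparisons (`compare_models`) force all configurations onto one
shared fold split, making the comparison paired; sweeps reuse one split
across all m for the same reason. All randomness descends from the single
experiment seed.

The feature-count sweep reports both ranking average precision and mean
per-label accuracy, since "average accuracy" on such a sweep can
reasonably mean either; on default synthetic data both peak at an
interior m (around 20) and decline as m approaches the full space.

## Numerical and design choices

* Log base 2 throughout; information scores are in bits.
* Plug-in probability estimates without smoothing in the scorers; the
  smoothing parameter s applies only to the classifier's priors and
  likelihood tables. s = 0 is accepted but can make a posterior 0/0, which
  raises with a message directing to s > 0.
* k defaults to 10, s to 1 — the canonical choices for this classifier
  family.
* Uniform m across labels by default; per-label m is representable in
  config but not swept.
* Fold count, seeds and greedy tie tolerance as above.
* Model serialisation is plain JSON with embedded training matrices;
  floats survive the round-trip exactly (tested bit-for-bit).

## Known limitations

* Binary symptoms only; ordinal severities must be binarised upstream.
* Brute-force distances are O(n²·m) per label; fine at n ≈ 10³, not
  designed for n ≫ 10⁴.
* Per-label posteriors ignore label correlations at prediction time; the
  generator's co-occurrence is exploited only implicitly through the
  feature sets.
* The mRMR implementation is the MID (difference) variant only.
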