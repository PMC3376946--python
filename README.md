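# realml

Multilabel syndrome diagnosis from binary symptom data, using a
**label-specific feature subspace** for every syndrome combined with the
**ML-kNN** Bayesian posterior — the REAL ("relevant feature for each
label") approach — plus the standard ranking-based multilabel evaluation
measures, a synthetic symptom–syndrome data generator, and a
cross-validation harness.

## Who this is for

Researchers modelling clinical diagnosis problems in which one patient can
carry several diagnostic categories at once (for example the co-occurring
syndrome patterns of Traditional Chinese Medicine), observed through a
questionnaire of binary symptoms/signs. The package takes a row-aligned
pair of binary matrices — instances × symptoms and instances × syndromes —
and fits, evaluates and compares multilabel classifiers on them.

## The method

**ML-kNN.** For each label *l*, a smoothed prior that the label is present,

    P(H1) = (s + Σᵢ yᵢₗ) / (2s + n),

and likelihood tables P(Eⱼ | H1), P(Eⱼ | H0), where Eⱼ is the event that
exactly *j* of an instance's *k* nearest neighbours (Hamming distance on
the binary symptom vectors) carry the label. The tables are estimated by
counting leave-one-out neighbourhoods on the training set, smoothed with
strength *s* (s = 1 is Laplace). A query's posterior

    P(H1 | Eⱼ) = P(H1) P(Eⱼ|H1) / [ P(H1) P(Eⱼ|H1) + P(H0) P(Eⱼ|H0) ]

is its ranking score f(x, l); thresholding at 0.5 gives the MAP prediction.

**REAL.** Not every symptom is informative for every syndrome. REAL first
scores each symptom against each label with a filter criterion — mutual
information (`mi`), information gain (`ig`), conditional-mutual-information
maximisation (`cmim`) or minimum-redundancy-maximum-relevance (`mrmr`) —
and keeps the top *m* symptoms per label. Each label then gets its own
neighbour geometry: its prior, likelihood tables and query neighbourhoods
are all computed in its private m-dimensional subspace. With m = d the
model reduces *exactly* to vanilla ML-kNN (tested bit-for-bit).

**Evaluation.** Five multilabel measures computed from the score matrix
f(xᵢ, y), the binary predictions and the truth: average precision,
coverage (raw and divided by Q), ranking loss, hamming loss and one-error,
plus per-syndrome accuracy. Ranks are deterministic (ties to the lower
label index); each measure is validated against a brute-force enumeration
oracle to 1e-12.

**Synthetic data.** Real patient data of this kind is rarely shareable, so
the package ships a generator: latent syndromes sampled sequentially with
logistic coupling (so syndromes co-occur), each syndrome boosting its
"specific" symptoms through a noisy-OR and suppressing its "negative"
symptoms multiplicatively, on top of a background symptom rate, with the
rest of the symptom panel pure noise. Defaults mirror a realistic inquiry
scale: 919 instances, 113 symptoms, 6 syndromes.

## Worked example

Compare REAL (IG selection, m = 20, k = 10, s = 1) against vanilla ML-kNN
under paired 10-fold cross-validation on a default synthetic dataset:

```python
import realml as rm
from realml.evaluation import ExperimentConfig, compare_models, comparison_frames
from realml.real import RealConfig
from realml.mlknn import MLkNNConfig

dataset, _ = rm.generate_dataset(rm.GeneratorConfig(seed=0))
knn = MLkNNConfig(k=10, s=1.0)
reports = compare_models(dataset, {
    "REAL":   ExperimentConfig(model="real",
                               real_config=RealConfig("ig", 20, knn),
                               knn_config=knn, n_folds=10, seed=0),
    "ML-kNN": ExperimentConfig(model="mlknn",
                               real_config=RealConfig("ig", 20, knn),
                               knn_config=knn, n_folds=10, seed=0),
})
metric_tbl, label_tbl = comparison_frames(reports)
print(metric_tbl)
```

which prints (mean ± std over the 10 folds):

```
                              REAL         ML-kNN
average_precision    0.937 ± 0.017  0.894 ± 0.020
coverage_raw         1.381 ± 0.154  1.580 ± 0.163
coverage_normalized  0.230 ± 0.026  0.263 ± 0.027
ranking_loss         0.064 ± 0.012  0.101 ± 0.016
hamming_loss         0.128 ± 0.009  0.167 ± 0.017
one_error            0.058 ± 0.030  0.119 ± 0.040
```

Average precision is higher and every loss is lower for REAL: restricting
each syndrome to its own 20 most informative symptoms removes the ~80
noise symptoms that otherwise dominate the shared Hamming geometry. The
second table (`label_tbl`) breaks the same comparison down into
per-syndrome recognition accuracy. Sweeping m over
{112, 100, 70, 60, 50, 40, 30, 20, 10, 5} with `feature_sweep` shows
average precision peaking at an interior subspace size (m ≈ 20) and
declining as m grows toward the full space.

The same experiments are available from the shell:

```bash
realml simulate --seed 0 --out-dir data/
realml compare --features data/features.csv --labels data/labels.csv \
    --method ig --num-features 20 --k 10 --out comparison.json
realml sweep   --features data/features.csv --labels data/labels.csv \
    --out sweep.csv --plot sweep.png
```

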