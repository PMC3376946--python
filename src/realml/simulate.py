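"""Synthetic multilabel symptom–syndrome data generator.

Emulates the structure of a clinical inquiry-scale dataset: a handful of
latent syndromes that co-occur, each emitting its own "specific" symptoms
(positive evidence) and suppressing its "negative" symptoms
(counter-evidence), on top of a large pool of irrelevant noise symptoms.

Generative model
----------------
Labels are sampled sequentially with logistic coupling to earlier labels,

    z_l ~ Bernoulli( logistic( alpha_l + sum_{j<l} w_{jl} z_j ) ),

so positive weights make syndromes co-occur.  Each symptom f is then an
independent Bernoulli draw whose probability combines a noisy-OR over the
active syndromes that list f as specific with a multiplicative suppression
for the active syndromes that list f as negative:

    p = 1 − (1 − q_base) · (1 − beta) ** #{active l : f specific for l}
    p ← p · (1 − gamma)  ** #{active l : f negative for l}

q_base is the background symptom rate, beta the specific-evidence boost,
gamma the negative-evidence suppression; all stay strictly inside (0, 1).

The default configuration mirrors the scale of the motivating study
(919 instances, 113 symptoms, 6 syndromes).  Its six profiles draw their
specific and negative sets from a shared pool of 30 relevant symptoms via
a rotation, so neighbouring syndromes share symptoms and the same symptom
can be specific for one syndrome and negative for another — as real
inquiry scales exhibit — while the remaining 83 symptoms are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import Dataset

__all__ = [
    "SyndromeProfile",
    "GeneratorConfig",
    "default_profiles",
    "sample_label_matrix",
    "symptom_probability",
    "generate_dataset",
]

SYNDROME_NAMES = [
    "damp_heat_spleen_stomach",
    "dampness_obstruction",
    "spleen_stomach_qi_deficiency",
    "spleen_stomach_deficiency_cold",
    "liver_stagnation",
    "stagnated_heat_liver_stomach",
]

# Marginal prevalences stay in the moderate 0.1-0.4 band; adjacent-label
# coupling of 0.7 on the logit scale makes neighbouring syndromes co-occur.
_BASE_LOGITS = [-0.6, -1.1, -1.2, -1.7, -1.3, -1.5]
_ADJACENT_COUPLING = 0.7

_POOL_SIZE = 30          # relevant-symptom pool shared across syndromes
_SPECIFIC_PER_LABEL = 8
_NEGATIVE_PER_LABEL = 8
_ROTATION_STRIDE = 5     # offset between consecutive syndromes' sets


@dataclass
class SyndromeProfile:
    """One latent syndrome: prevalence, coupling, and its symptom sets."""

    label_name: str
    base_logit: float
    co_weights: np.ndarray  # coupling to each *earlier* label
    specific_features: list[int]
    negative_features: list[int]

    def __post_init__(self) -> None:
        self.co_weights = np.asarray(self.co_weights, dtype=float)
        if set(self.specific_features) & set(self.negative_features):
            raise ValueError(
                "specific and negative feature sets must be disjoint "
                f"for {self.label_name}"
            )


@dataclass
class GeneratorConfig:
    n_instances: int = 919
    n_features: int = 113
    profiles: list[SyndromeProfile] = field(default_factory=list)
    q_base: float = 0.15
    beta: float = 0.55
    gamma: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.profiles:
            self.profiles = default_profiles(self.n_features)
        for p in (self.q_base, self.beta, self.gamma):
            if not 0.0 < p < 1.0:
                raise ValueError("q_base, beta, gamma must lie strictly in (0, 1)")
        if self.n_instances < 1 or self.n_features < 1:
            raise ValueError("n_instances and n_features must be >= 1")
        for prof in self.profiles:
            for j in prof.specific_features + prof.negative_features:
                if not 0 <= j < self.n_features:
                    raise ValueError(
                        f"feature index {j} out of range for {prof.label_name}"
                    )

    @property
    def n_labels(self) -> int:
        return len(self.profiles)


def default_profiles(n_features: int = 113) -> list[SyndromeProfile]:
    """Six syndrome profiles over a shared 30-symptom relevant pool.

    Syndrome l takes pool slots (5l .. 5l+7) mod 30 as specific and
    (5l+8 .. 5l+15) mod 30 as negative, so consecutive syndromes overlap
    and a symptom can play opposite roles for different syndromes.
    """
    if n_features < _POOL_SIZE:
        raise ValueError(f"need at least {_POOL_SIZE} features, got {n_features}")
    profiles = []
    for l, name in enumerate(SYNDROME_NAMES):
        start = _ROTATION_STRIDE * l
        specific = [(start + j) % _POOL_SIZE for j in range(_SPECIFIC_PER_LABEL)]
        negative = [
            (start + _SPECIFIC_PER_LABEL + j) % _POOL_SIZE
            for j in range(_NEGATIVE_PER_LABEL)
        ]
        co = np.zeros(l)
        if l > 0:
            co[l - 1] = _ADJACENT_COUPLING
        profiles.append(
            SyndromeProfile(
                label_name=name,
                base_logit=_BASE_LOGITS[l],
                co_weights=co,
                specific_features=specific,
                negative_features=negative,
            )
        )
    return profiles


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def sample_label_matrix(config: GeneratorConfig,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Sequentially sampled (n × Q) binary label matrix with co-occurrence."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, Q = config.n_instances, config.n_labels
    Z = np.zeros((n, Q), dtype=np.int8)
    for l, prof in enumerate(config.profiles):
        logit = prof.base_logit + Z[:, :l] @ prof.co_weights
        Z[:, l] = rng.random(n) < _logistic(logit)
    return Z


def symptom_probability(z, feature_index: int, config: GeneratorConfig) -> float:
    """Emission probability of one symptom given an active-syndrome vector."""
    z = np.asarray(z).ravel()
    if z.size != config.n_labels:
        raise ValueError(f"z must have length {config.n_labels}")
    n_spec = sum(
        1 for l, prof in enumerate(config.profiles)
        if z[l] == 1 and feature_index in prof.specific_features
    )
    n_neg = sum(
        1 for l, prof in enumerate(config.profiles)
        if z[l] == 1 and feature_index in prof.negative_features
    )
    p = 1.0 - (1.0 - config.q_base) * (1.0 - config.beta) ** n_spec
    return float(p * (1.0 - config.gamma) ** n_neg)


def _probability_matrix(Z: np.ndarray, config: GeneratorConfig) -> np.ndarray:
    """Vectorised emission probabilities for every (instance, symptom) cell."""
    Q, d = config.n_labels, config.n_features
    S = np.zeros((Q, d))
    N = np.zeros((Q, d))
    for l, prof in enumerate(config.profiles):
        S[l, prof.specific_features] = 1.0
        N[l, prof.negative_features] = 1.0
    n_spec = Z.astype(float) @ S  # (n, d) counts of active specific parents
    n_neg = Z.astype(float) @ N
    p = 1.0 - (1.0 - config.q_base) * (1.0 - config.beta) ** n_spec
    return p * (1.0 - config.gamma) ** n_neg


def generate_dataset(config: GeneratorConfig
                     ) -> tuple[Dataset, list[SyndromeProfile]]:
    """Sample a full dataset; returns the planted profiles alongside it."""
    rng = np.random.default_rng(config.seed)
    Z = sample_label_matrix(config, rng)
    P = _probability_matrix(Z, config)
    X = (rng.random(P.shape) < P).astype(np.int8)
    feature_names = [f"sym_{j:03d}" for j in range(config.n_features)]
    label_names = [prof.label_name for prof in config.profiles]
    return Dataset(X, Z, feature_names, label_names), config.profiles
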