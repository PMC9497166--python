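"""Synthetic nodule tables with planted effects and a simulated CADx.

Each sample draws one level per categorical feature independently from
configurable marginals.  The malignancy label follows a logistic
model:

    logit = beta0 + sum_i beta_i + sum_(i,j) gamma_(i,j) + u,
    label ~ Bernoulli(sigmoid(logit)),

with first-order log-odds effects beta on planted levels, at least one
pairwise interaction gamma on a planted level pair, and a latent
severity term u ~ Normal(0, latent_sd^2) standing for grey-scale image
evidence outside the feature lexicon.  The simulated CADx emulates a
CNN reading the B-mode images: it sees the grey-scale part of the
logit (including u) through noise, but is blind to the colour-Doppler
features (``cadx_blind``), which only the radiologist records:

    cadx_score = sigmoid(slope * (visible logit) + Normal(0, sigma)).

The score is therefore correlated with the label, carries independent
error, and the lexicon holds complementary vascular information the
CADx lacks -- the premise under which combining the two beats either
alone.

Two shipped regimes, both planting the interaction
(vascular_localization=perinodular, vascular_morphology=untwisted)
with odds multiplier 2.35:

* ``default_generator_spec`` -- moderate effects, prevalence near
  0.42; other-effect variance kept small so the marginal 2x2 odds
  ratio of the planted pair stays close to its conditional 2.35
  (logistic odds ratios attenuate under marginalization).
* ``hybrid_generator_spec`` -- strong grey-scale and Doppler effects,
  larger latent variance, CADx noise set so the standalone score AUC
  sits near 0.87; the regime for studying the human-AI hybrid gain.
  Its dictionary discretizes the CADx score into octile levels to
  preserve the score's granularity inside the factorization machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .feature_space import FeatureDictionary, default_dictionary
from .gafm import sigmoid

__all__ = [
    "GeneratorSpec",
    "default_generator_spec",
    "hybrid_generator_spec",
    "generate",
    "holdout_split",
]

PLANTED_PAIR = (
    ("vascular_localization", "perinodular"),
    ("vascular_morphology", "untwisted"),
)
PLANTED_OR = 2.35


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorSpec:
    """Ground-truth model for the synthetic cohort.

    marginals  : per feature, level probabilities (must sum to 1)
    intercept  : beta0 on the logit scale
    betas      : {(feature, level): log-odds effect}
    interactions : {((f1, l1), (f2, l2)): log-odds effect when both
                    levels are drawn}
    latent_sd  : SD of the grey-scale-only severity term u
    cadx_sigma : SD of the CADx observation noise
    cadx_slope : miscalibration slope of the CADx link
    cadx_blind : features whose effects the CADx cannot see (the
                 colour-Doppler descriptors by default)
    """

    dictionary: FeatureDictionary = field(default_factory=default_dictionary)
    marginals: dict[str, list[float]] = field(default_factory=dict)
    intercept: float = -0.90
    betas: dict[tuple[str, str], float] = field(default_factory=dict)
    interactions: dict[tuple[tuple[str, str], tuple[str, str]], float] = field(
        default_factory=dict
    )
    latent_sd: float = 0.30
    cadx_sigma: float = 0.50
    cadx_slope: float = 1.0
    cadx_blind: tuple[str, ...] = (
        "vascular_localization", "vascular_morphology",
    )
    n: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GeneratorError("n must be >= 1")
        if self.cadx_sigma < 0 or self.latent_sd < 0:
            raise GeneratorError("noise scales must be >= 0")
        for name, probs in self.marginals.items():
            levels = self.dictionary.levels_of(name)
            if len(probs) != len(levels):
                raise GeneratorError(
                    f"marginals for {name!r} have {len(probs)} entries, "
                    f"feature has {len(levels)} levels"
                )
            if abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise GeneratorError(
                    f"marginals for {name!r} must be a probability vector"
                )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "marginals": self.marginals,
            "betas": {f"{f}={l}": v for (f, l), v in self.betas.items()},
            "interactions": {
                f"{f1}={l1}&{f2}={l2}": v
                for ((f1, l1), (f2, l2)), v in self.interactions.items()
            },
            "latent_sd": self.latent_sd,
            "cadx_sigma": self.cadx_sigma,
            "cadx_slope": self.cadx_slope,
            "cadx_blind": list(self.cadx_blind),
            "n": self.n,
            "seed": self.seed,
        }


DEFAULT_MARGINALS = {
    "composition": [0.10, 0.10, 0.30, 0.50],
    "echogenicity": [0.05, 0.15, 0.25, 0.45, 0.10],
    "margin": [0.45, 0.25, 0.25, 0.05],
    "shape": [0.70, 0.30],
    "echogenic_foci": [0.45, 0.10, 0.15, 0.05, 0.25],
    "vascular_localization": [0.20, 0.30, 0.15, 0.20, 0.15],
    "vascular_morphology": [0.55, 0.45],
    "halo": [0.55, 0.30, 0.15],
    "posterior_features": [0.55, 0.20, 0.15, 0.10],
    "echo_texture": [0.60, 0.40],
}


def default_generator_spec(
    n: int = 3000, seed: int = 0, **overrides
) -> GeneratorSpec:
    """Default cohort: planted pair OR 2.35, five moderate first-order
    effects, the remaining levels pure noise, prevalence near 0.42.

    Effect variance is deliberately modest so that the observable
    marginal odds ratio of the planted pair remains close to the
    planted conditional value (within the attenuation a logistic model
    suffers when independent effects are marginalized out).
    """
    betas = {
        ("margin", "irregular"): 0.40,
        ("shape", "taller-than-wide"): 0.36,
        ("echogenicity", "marked-hypoechoic"): 0.32,
        ("echogenic_foci", "punctate"): 0.40,
        ("composition", "solid"): 0.20,
    }
    interactions = {PLANTED_PAIR: float(np.log(PLANTED_OR))}
    spec = GeneratorSpec(
        marginals={k: list(v) for k, v in DEFAULT_MARGINALS.items()},
        betas=dict(betas),
        interactions=dict(interactions),
        n=n,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(spec, key, value)
    spec.__post_init__()
    return spec


def hybrid_generator_spec(
    n: int = 6000, seed: int = 0, cadx_bins: int = 8, **overrides
) -> GeneratorSpec:
    """High-signal regime for studying the human-AI hybrid gain.

    Strong grey-scale effects, strong Doppler effects (which the CADx
    cannot see), a large latent severity term and CADx noise
    calibrated so the standalone score AUC falls near 0.87, mirroring
    the regime where a hybrid of radiologist features and CADx beats
    either constituent.  The dictionary discretizes the CADx score
    into ``cadx_bins`` quantile levels.
    """
    from .feature_space import build_dictionary, default_dictionary_spec

    dict_spec = default_dictionary_spec()
    dict_spec["cadx"]["mode"] = "quantile"
    dict_spec["cadx"]["bins"] = cadx_bins
    betas = {
        # grey-scale (visible to the CADx)
        ("margin", "irregular"): 2.4,
        ("shape", "taller-than-wide"): 2.2,
        ("echogenicity", "marked-hypoechoic"): 2.0,
        ("echogenic_foci", "punctate"): 2.4,
        ("composition", "solid"): 1.2,
        ("halo", "thick"): 1.5,
        ("echo_texture", "heterogeneous"): 1.2,
        ("posterior_features", "shadowing"): 1.0,
        # colour-Doppler (human-only)
        ("vascular_localization", "central"): 2.2,
        ("vascular_morphology", "twisted"): -0.8,
    }
    spec = GeneratorSpec(
        dictionary=build_dictionary(dict_spec),
        marginals={k: list(v) for k, v in DEFAULT_MARGINALS.items()},
        intercept=-3.73,
        betas=betas,
        interactions={PLANTED_PAIR: float(np.log(PLANTED_OR))},
        latent_sd=2.0,
        cadx_sigma=0.72,
        cadx_slope=0.6,
        n=n,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(spec, key, value)
    spec.__post_init__()
    return spec


def generate(
    spec: GeneratorSpec, n: int | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic cohort table and its ground truth.

    Returns a records table (one column per categorical feature, plus
    ``cadx_score`` and ``label``) and a ground-truth dict holding the
    planted effects and the per-sample true logits.
    """
    n = spec.n if n is None else n
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    d = spec.dictionary
    cat_features = [
        (name, levels) for name, levels in d.features
        if name != d.cadx_feature
    ]

    blind = set(spec.cadx_blind)
    columns: dict[str, np.ndarray] = {}
    logit = np.full(n, spec.intercept, dtype=float)
    visible = np.full(n, spec.intercept, dtype=float)
    for name, levels in cat_features:
        probs = spec.marginals.get(name)
        if probs is None:
            probs = [1.0 / len(levels)] * len(levels)
        draws = rng.choice(len(levels), size=n, p=probs)
        columns[name] = np.array(levels, dtype=object)[draws]
        for li, level in enumerate(levels):
            beta = spec.betas.get((name, level), 0.0)
            if beta:
                term = beta * (draws == li)
                logit += term
                if name not in blind:
                    visible += term
    for ((f1, l1), (f2, l2)), gamma in spec.interactions.items():
        both = (columns[f1] == l1) & (columns[f2] == l2)
        logit += gamma * both
        if f1 not in blind and f2 not in blind:
            visible += gamma * both

    u = rng.normal(0.0, spec.latent_sd, n) if spec.latent_sd > 0 else 0.0
    full_logit = logit + u
    label = rng.random(n) < sigmoid(full_logit)
    noise = rng.normal(0.0, spec.cadx_sigma, n) if spec.cadx_sigma > 0 else 0.0
    cadx = sigmoid(spec.cadx_slope * (visible + u) + noise)

    table = pd.DataFrame(columns)
    table["cadx_score"] = cadx
    table["label"] = label.astype(int)
    truth = {
        "spec": spec.to_dict(),
        "prevalence": float(label.mean()),
        "true_logit": [float(v) for v in full_logit],
    }
    return table, truth


def holdout_split(
    table: pd.DataFrame, fraction: float = 0.25, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label-stratified train/test split; ``fraction`` goes to test."""
    if not 0.0 < fraction < 1.0:
        raise GeneratorError("fraction must lie strictly between 0 and 1")
    n_test = int(round(len(table) * fraction))
    if n_test < 2 or len(table) - n_test < 2:
        raise GeneratorError("split would produce a degenerate partition")
    train, test = train_test_split(
        table, test_size=fraction, random_state=seed,
        stratify=table["label"],
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)
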