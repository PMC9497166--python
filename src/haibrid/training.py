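"""Two-step GAFM training, feature ranking/selection, and baselines.

Step 1 trains the ungated model (every co-active pair interacts, i.e.
an AFM).  The dataset-average attention of each pair is then compared
with a threshold epsilon; pairs at or below it are dropped (the gate).
Step 2 retrains with the surviving pairs plus all first-order terms.
After convergence the first-order weights W_i and the pair coefficients
mean_attention(i,j) * <V_i, V_j> are ranked together, the top-k kept
(15 by default, matching a Kwak-style scorecard length), and their
coefficients softmax-normalized into weights summing to 1.

Optimization notes.  The factorization-machine objective is bilinear
in the embeddings and non-convex; which pairwise interactions a single
fit amplifies depends visibly on the initialization.  Three choices
stabilize interaction recovery at desk-scale sample sizes:

* a small number of seeded restarts (default 2); predictions come from
  the restart with the lowest training loss, while the importance and
  coefficient estimates used for gating and ranking are averaged over
  restarts (initialization-dependent spurious interactions average
  out, consistently supported ones persist);
* mild L2 on the embedding matrix only (the first-order weights stay
  unpenalized, so the gate-empty model remains a plain logistic fit);
* a reduced learning rate on the attention network, so attention
  follows the embeddings instead of collapsing early onto an
  arbitrary interaction direction (softmax winner-take-all leaves no
  recovery gradient once a pair's attention reaches zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression

from .feature_space import EncodedDataset, decode_identity
from .gafm import (
    GAFMParameters,
    InteractionImportance,
    _batch_backward,
    _batch_forward,
    apply_gate,
    average_attention,
    bce_loss,
    forward_batch,
    init_parameters,
)

__all__ = [
    "TrainingConfig",
    "SelectedFeatureSet",
    "TrainingResult",
    "train_step1",
    "train_step2",
    "two_step_train",
    "rank_and_select",
    "fit_baselines",
    "BaselineModels",
    "max_combination",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization, gating and selection settings.

    ``gate_epsilon=None`` uses the data-adaptive default: the mean of
    all per-pair average attentions.  ``weight_mode`` selects how the
    selected coefficients are normalized: ``"softmax"`` (exponential
    weights over the signed coefficients) or ``"signed_share"``
    (coefficient / sum |coefficient|, sign preserved).
    ``attention_average`` picks the divisor of the dataset-average
    attention: ``"total"`` (divide by N; pairs are weighted by their
    co-occurrence support) or ``"coactive"`` (mean over co-active
    samples only).
    """

    embedding_dim: int = 2
    attention_hidden: int = 8
    gate_epsilon: float | None = None
    learning_rate: float = 1e-2
    batch_size: int = 256
    max_epochs: int = 150
    tol: float = 1e-6
    patience: int = 20
    top_k: int = 15
    seed: int = 0
    bias: bool = True
    init_scale: float = 0.05
    weight_mode: str = "softmax"
    attention_average: str = "total"
    embed_l2: float = 3e-4
    attention_lr_scale: float = 0.1
    restarts: int = 3

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.weight_mode not in ("softmax", "signed_share"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")


class SingleClassError(ValueError):
    """Training requires both benign and malignant samples."""


def _check_two_classes(dataset: EncodedDataset) -> np.ndarray:
    if dataset.y is None:
        raise SingleClassError("dataset carries no labels")
    y = dataset.y.astype(float)
    if y.min() == y.max():
        raise SingleClassError("dataset contains a single class")
    return y


class _Adam:
    """Adaptive-moment SGD over a dict of arrays (and the scalar bias)."""

    def __init__(self, keys, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: None for k in keys}
        self.v = {k: None for k in keys}
        self.t = 0

    def step(self, params: GAFMParameters, grads: dict) -> None:
        self.t += 1
        for key, g in grads.items():
            g = np.asarray(g, dtype=float)
            if self.m[key] is None:
                self.m[key] = np.zeros_like(g)
                self.v[key] = np.zeros_like(g)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            delta = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if key == "bias":
                params.bias -= float(delta)
            else:
                getattr(params, key).__isub__(delta)


def _fit(
    dataset: EncodedDataset,
    config: TrainingConfig,
    params: GAFMParameters,
    log: Callable[[str], None] | None = None,
    shuffle_seed: int | None = None,
) -> tuple[GAFMParameters, list[float]]:
    """Minimize mean cross-entropy; stops when the per-epoch training
    loss improves by less than ``tol`` for ``patience`` consecutive
    epochs (or at ``max_epochs``)."""
    y = _check_two_classes(dataset)
    params = params.copy()
    keys = ["W", "V", "attn_W", "attn_b", "attn_p"]
    if params.use_bias:
        keys.append("bias")
    opt = _Adam(keys, config.learning_rate)
    rng = np.random.default_rng(
        config.seed if shuffle_seed is None else shuffle_seed
    )
    n = dataset.n_samples
    history: list[float] = []
    best = math.inf
    stall = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        if config.learning_rate > 0:
            batch_losses = []
            for start in range(0, n, config.batch_size):
                batch = order[start : start + config.batch_size]
                cache = _batch_forward(dataset, params, batch)
                batch_losses.append(
                    bce_loss(cache.prob, y[batch]) * batch.size
                )
                grads = _batch_backward(dataset, params, cache, y[batch], batch)
                if config.embed_l2:
                    grads["V"] = grads["V"] + config.embed_l2 * params.V
                if config.attention_lr_scale != 1.0:
                    for key in ("attn_W", "attn_b", "attn_p"):
                        grads[key] = grads[key] * config.attention_lr_scale
                if not params.use_bias:
                    grads.pop("bias", None)
                opt.step(params, grads)
            # epoch training loss tracked as the sample-weighted mean of
            # the pre-update batch losses (one full extra forward pass
            # per epoch is the single largest cost otherwise)
            loss = float(np.sum(batch_losses) / n)
        else:
            loss = bce_loss(forward_batch(dataset, params)[1], y)
        history.append(loss)
        if log is not None:
            log(f"epoch {epoch + 1}: loss {loss:.6f}")
        if best - loss < config.tol:
            stall += 1
            if stall >= config.patience:
                break
        else:
            stall = 0
        best = min(best, loss)
    return params, history


def _restart_seed(config: TrainingConfig, r: int) -> int:
    return (config.seed * 100003 + 7919 * r) % (2 ** 31 - 1)


def _train_step1_restarts(
    dataset: EncodedDataset,
    config: TrainingConfig,
    log: Callable[[str], None] | None = None,
) -> list[tuple[GAFMParameters, list[float]]]:
    """Seeded restarts of the ungated fit, in restart order."""
    fits = []
    for r in range(config.restarts):
        seed = _restart_seed(config, r)
        params = init_parameters(
            dataset.width, config.embedding_dim, config.attention_hidden,
            seed=seed, scale=config.init_scale, use_bias=config.bias,
        )
        fits.append(_fit(dataset, config, params, log, shuffle_seed=seed))
    return fits


def train_step1(
    dataset: EncodedDataset,
    config: TrainingConfig,
    params: GAFMParameters | None = None,
    log: Callable[[str], None] | None = None,
) -> tuple[GAFMParameters, list[float]]:
    """Ungated (AFM-style) training: every co-active pair interacts.

    With ``params=None`` the configured number of seeded restarts is
    run and the fit with the lowest final training loss is returned;
    an explicit ``params`` initialization trains exactly once from it.
    """
    if params is not None:
        return _fit(dataset, config, replace(params.copy(), gamma=None), log)
    fits = _train_step1_restarts(dataset, config, log)
    return min(fits, key=lambda f: f[1][-1])


def train_step2(
    dataset: EncodedDataset,
    config: TrainingConfig,
    params: GAFMParameters,
    log: Callable[[str], None] | None = None,
) -> tuple[GAFMParameters, list[float]]:
    """Retrain with the gate set fixed; first-order terms stay active."""
    if params.gamma is None:
        raise ValueError("step 2 requires a gate set (run apply_gate first)")
    return _fit(dataset, config, params, log)


@dataclass
class TrainingResult:
    params: GAFMParameters
    importance: InteractionImportance
    epsilon: float
    history_step1: list[float]
    history_step2: list[float]
    coefficients: dict | None = None   # ensemble ranking coefficients


def resolve_epsilon(
    importance: InteractionImportance, config: TrainingConfig
) -> float:
    """Config epsilon, or the data-adaptive default mean + 1 SD.

    Most pairwise attention at desk-scale sample sizes is noise; a
    threshold one standard deviation above the mean keeps the gate
    strict (typically a few tens of retained pairs) while genuinely
    supported interactions sit far above it.
    """
    if config.gate_epsilon is not None:
        return config.gate_epsilon
    if not importance.mean:
        return -math.inf
    values = np.array(list(importance.mean.values()))
    return float(values.mean() + values.std())


def _ensemble_importance(
    imps: Sequence[InteractionImportance],
) -> InteractionImportance:
    """Per-pair mean attention averaged across restarts.

    All restarts see the same data, so the co-active pair sets and
    counts coincide; only the attention values differ.
    """
    base = imps[0]
    if len(imps) == 1:
        return base
    mean = {
        pair: float(np.mean([imp.mean[pair] for imp in imps]))
        for pair in base.mean
    }
    return InteractionImportance(
        mean=mean, count=dict(base.count),
        n_samples=base.n_samples, divisor=base.divisor,
    )


def two_step_train(
    dataset: EncodedDataset,
    config: TrainingConfig,
    params: GAFMParameters | None = None,
    log: Callable[[str], None] | None = None,
) -> TrainingResult:
    """Full pipeline: AFM training, gate, retrain with retained pairs.

    Runs the configured restarts through both steps.  The gate is set
    once, from the restart-averaged step-1 attention importance, so
    every restart retrains against the same interaction set.  The
    returned parameters are the best step-2 fit by training loss; the
    returned importance and ranking coefficients are restart averages
    of the step-2 models.
    """
    if params is not None:
        fits1 = [_fit(dataset, config, replace(params.copy(), gamma=None),
                      log)]
    else:
        fits1 = _train_step1_restarts(dataset, config, log)
    imps1 = [
        average_attention(dataset, p, divisor=config.attention_average)
        for p, _ in fits1
    ]
    importance1 = _ensemble_importance(imps1)
    epsilon = resolve_epsilon(importance1, config)
    gamma = apply_gate(importance1, epsilon)
    if log is not None:
        log(f"gate: epsilon={epsilon:.6g}, retained {len(gamma)} of "
            f"{len(importance1.mean)} pairs")

    # step 2 re-trains from fresh (seeded) initializations: the gated
    # model is a different, sparser hypothesis and inheriting step-1
    # embeddings re-imports the interaction noise the gate removed
    fits2 = []
    for r in range(len(fits1)):
        seed2 = _restart_seed(config, r) + 1
        gated = replace(
            init_parameters(
                dataset.width, config.embedding_dim,
                config.attention_hidden, seed=seed2,
                scale=config.init_scale, use_bias=config.bias,
            ),
            gamma=gamma,
        )
        fits2.append(_fit(dataset, config, gated, log, shuffle_seed=seed2))
    best_idx = int(np.argmin([h[-1] for _, h in fits2]))
    step2_params, hist2 = fits2[best_idx]

    imps2 = [
        average_attention(dataset, p, divisor=config.attention_average)
        for p, _ in fits2
    ]
    importance2 = _ensemble_importance(imps2)
    # ensemble ranking coefficients: W_i averaged over the final gated
    # fits; pair coefficients alpha(i,j) * <V_i, V_j> averaged over the
    # gated AND the ungated fits (every converged model estimates the
    # same quantity for a retained pair, and the wider ensemble is
    # visibly more stable at desk-scale n)
    coefficients: dict = {
        int(i): float(np.mean([p.W[i] for p, _ in fits2]))
        for i in range(dataset.width)
    }
    pair_sets = [_pair_coefficients(p, imp)
                 for (p, _), imp in zip(fits2, imps2)]
    pair_sets += [_pair_coefficients(p, imp)
                  for (p, _), imp in zip(fits1, imps1)]
    for pair in pair_sets[0]:
        coefficients[pair] = float(
            np.mean([ps[pair] for ps in pair_sets if pair in ps])
        )
    return TrainingResult(
        params=step2_params,
        importance=importance2,
        epsilon=epsilon,
        history_step1=fits1[best_idx][1],
        history_step2=hist2,
        coefficients=coefficients,
    )


# ---------------------------------------------------------------------------
# Ranking and selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectedEntry:
    identity: int | tuple[int, int]
    name: str
    coefficient: float
    weight: float
    rank: int


@dataclass
class SelectedFeatureSet:
    """Top-ranked first- and second-order features with normalized weights.

    Entries are sorted by descending normalized weight; the K weights
    sum to 1 (softmax mode) or have absolute values summing to 1
    (signed-share mode).
    """

    entries: list[SelectedEntry]
    weight_mode: str

    @property
    def K(self) -> int:
        return len(self.entries)

    def to_dict(self) -> dict:
        return {
            "weight_mode": self.weight_mode,
            "entries": [
                {
                    "identity": list(e.identity)
                    if isinstance(e.identity, tuple) else e.identity,
                    "name": e.name,
                    "coefficient": e.coefficient,
                    "weight": e.weight,
                    "rank": e.rank,
                }
                for e in self.entries
            ],
        }


def _pair_coefficients(
    params: GAFMParameters, importance: InteractionImportance
) -> dict[tuple[int, int], float]:
    """Pair coefficient = mean attention * <V_i, V_j>: the pair's
    average additive logit contribution when co-active (for one-hot
    features e_i = V_i)."""
    pairs = importance.mean if params.gamma is None else {
        p: a for p, a in importance.mean.items() if p in params.gamma
    }
    return {
        (i, j): a * float(params.V[i] @ params.V[j])
        for (i, j), a in pairs.items()
    }


def rank_and_select(
    params: GAFMParameters,
    importance: InteractionImportance,
    config: TrainingConfig,
    dictionary=None,
    coefficients: dict | None = None,
) -> SelectedFeatureSet:
    """Rank all first-order weights and retained-pair coefficients,
    keep the ``top_k`` largest, and normalize their coefficients.

    ``coefficients`` (identity -> raw coefficient) overrides the
    single-model coefficients; :func:`two_step_train` supplies its
    restart-averaged values through it.  Ties in the raw coefficient
    are broken by dictionary position (single features first, then
    pairs in lexicographic position order) so the selection is
    deterministic.
    """
    if coefficients is not None:
        items = list(coefficients.items())
    else:
        items = [(int(i), float(w)) for i, w in enumerate(params.W)]
        items.extend(_pair_coefficients(params, importance).items())

    def sort_key(item):
        identity, coef = item
        pos = (0, identity, 0) if isinstance(identity, int) else (
            1, identity[0], identity[1]
        )
        return (-coef, pos)

    items.sort(key=sort_key)
    selected = items[: min(config.top_k, len(items))]
    coefs = np.array([c for _, c in selected])
    if config.weight_mode == "softmax":
        z = np.exp(coefs - coefs.max())
        weights = z / z.sum()
    else:
        total = np.abs(coefs).sum()
        weights = coefs / total if total > 0 else np.full_like(coefs, 0.0)

    entries = [
        SelectedEntry(
            identity=ident,
            name=decode_identity(ident, dictionary) if dictionary is not None
            else str(ident),
            coefficient=float(c),
            weight=float(w),
            rank=r + 1,
        )
        for r, ((ident, c), w) in enumerate(zip(selected, weights))
    ]
    return SelectedFeatureSet(entries=entries, weight_mode=config.weight_mode)


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

@dataclass
class BaselineModels:
    lr0: LogisticRegression
    lr1: LogisticRegression
    lr1_support: np.ndarray
    afm: GAFMParameters

    def predict_lr0(self, X: np.ndarray) -> np.ndarray:
        return self.lr0.predict_proba(X)[:, 1]

    def predict_lr1(self, X: np.ndarray) -> np.ndarray:
        return self.lr1.predict_proba(X[:, self.lr1_support])[:, 1]


def _logistic(seed: int = 0) -> LogisticRegression:
    # C=inf disables the ridge penalty: a plain maximum-likelihood fit
    return LogisticRegression(
        C=np.inf, solver="lbfgs", max_iter=2000, random_state=seed
    )


def fit_baselines(
    dataset: EncodedDataset, config: TrainingConfig
) -> BaselineModels:
    """Control models: LR as plain classifier (LR0), LR as selector +
    classifier (LR1: rank |weights|, keep top_k, refit), and the AFM
    (ungated GAFM)."""
    y = _check_two_classes(dataset)
    lr0 = _logistic(config.seed).fit(dataset.X, y)
    order = np.argsort(-np.abs(lr0.coef_[0]), kind="stable")
    support = np.sort(order[: min(config.top_k, dataset.width)])
    lr1 = _logistic(config.seed).fit(dataset.X[:, support], y)
    afm, _ = train_step1(dataset, config)
    return BaselineModels(lr0=lr0, lr1=lr1, lr1_support=support, afm=afm)


def max_combination(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Return the higher malignancy probability of the two methods."""
    return np.maximum(np.asarray(p1, dtype=float), np.asarray(p2, dtype=float))
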