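"""Cross-validation, AUC, odds ratios and method comparisons.

Fold partitioning balances not only the class labels but the marginal
frequency of every feature level across folds (a greedy interpretation
of distribution-balanced stratified cross-validation): samples are
visited in seeded random order and each is placed into the smallest
fold where it least perturbs the per-level and per-label proportions.
Plain label-stratified folding is available as a fallback mode.

Per-fold AUCs of competing methods on identical partitions are
compared with paired two-tailed t-tests; unpaired tests serve
cross-group comparisons.  These fold-level t-tests mirror common
practice but are known to be anti-conservative; a corrected-resampled
variant (Nadeau-Bengio variance inflation) is available and off by
default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .feature_space import EncodedDataset
from .gafm import apply_gate, average_attention, forward_batch
from .training import (
    TrainingConfig,
    fit_baselines,
    max_combination,
    train_step1,
    train_step2,
    two_step_train,
    _logistic,
)

__all__ = [
    "FoldAssignment",
    "ComparisonResult",
    "balanced_partition",
    "stratified_partition",
    "auc",
    "odds_ratio",
    "compare_methods",
    "run_cv_experiment",
    "CV_METHODS",
]


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Fold partitioning
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    fold: np.ndarray            # fold index per sample
    k: int
    label_proportions: np.ndarray       # per-fold malignant fraction
    level_deviation: np.ndarray         # per-fold mean |level freq - global|

    def indices(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, test_idx) for fold f."""
        test = np.flatnonzero(self.fold == f)
        train = np.flatnonzero(self.fold != f)
        return train, test


def _fold_diagnostics(
    dataset: EncodedDataset, fold: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    y = dataset.y.astype(float)
    M = np.column_stack([(dataset.X > 0).astype(float), y])
    global_p = M.mean(axis=0)
    props = np.empty(k)
    devs = np.empty(k)
    for f in range(k):
        sel = fold == f
        props[f] = y[sel].mean()
        devs[f] = np.abs(M[sel].mean(axis=0)[:-1] - global_p[:-1]).mean()
    return props, devs


def balanced_partition(
    dataset: EncodedDataset, k: int, seed: int = 0
) -> FoldAssignment:
    """Greedy distribution-balanced stratified k-fold assignment.

    Each sample (in seeded random order) goes to the fold of minimal
    current size that minimizes the summed squared deviation of that
    fold's per-level and per-label proportions from the global ones.
    Deterministic given the seed.
    """
    n = dataset.n_samples
    if not 2 <= k <= n:
        raise EvaluationError(f"need 2 <= k <= N, got k={k}, N={n}")
    if dataset.y is None:
        raise EvaluationError("labels required for stratified partitioning")
    y = dataset.y.astype(int)
    M = (dataset.X > 0).astype(float)
    global_p = M.mean(axis=0)

    # exact per-fold class quotas: fold sizes differ by <= 1 and each
    # fold's positive count is within one sample of its proportional
    # share, as in plain stratified k-fold
    sizes = np.full(k, n // k) + (np.arange(k) < n % k)
    n_pos = int(y.sum())
    q_pos = np.full(k, n_pos // k) + (np.arange(k) < n_pos % k)
    quota = np.stack([sizes - q_pos, q_pos], axis=1)  # (k, 2)
    if quota.min() < 0:
        raise EvaluationError(
            "class too small to stratify over this many folds"
        )

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    counts = np.zeros((k, M.shape[1]))
    filled = np.zeros(k, dtype=int)
    fold = np.empty(n, dtype=int)
    for s in order:
        c = y[s]
        eligible = np.flatnonzero(quota[:, c] > 0)
        # level proportions of each eligible fold after adding s
        new_props = (counts[eligible] + M[s]) / (filled[eligible, None] + 1)
        cost = ((new_props - global_p) ** 2).sum(axis=1)
        f = int(eligible[np.argmin(cost)])
        fold[s] = f
        counts[f] += M[s]
        filled[f] += 1
        quota[f, c] -= 1
    props, devs = _fold_diagnostics(dataset, fold, k)
    return FoldAssignment(
        fold=fold, k=k, label_proportions=props, level_deviation=devs
    )


def stratified_partition(
    dataset: EncodedDataset, k: int, seed: int = 0
) -> FoldAssignment:
    """Plain label-stratified k-fold (fallback mode)."""
    n = dataset.n_samples
    if not 2 <= k <= n:
        raise EvaluationError(f"need 2 <= k <= N, got k={k}, N={n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    slot = 0
    for cls in (0, 1):
        idx = np.flatnonzero(dataset.y == cls)
        idx = rng.permutation(idx)
        for i, s in enumerate(idx):
            fold[s] = (slot + i) % k
        slot += len(idx)
    props, devs = _fold_diagnostics(dataset, fold, k)
    return FoldAssignment(
        fold=fold, k=k, label_proportions=props, level_deviation=devs
    )


def random_partition(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Size-balanced but otherwise unconstrained folds (for contrast)."""
    rng = np.random.default_rng(seed)
    fold = np.arange(n) % k
    return rng.permutation(fold)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC (concordance probability with tie correction)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC needs both classes")
    ranks = stats.rankdata(scores)
    return float(
        (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    )


def odds_ratio(
    present: np.ndarray,
    labels: np.ndarray,
    confidence: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """2x2 odds ratio of feature presence vs malignancy with Woolf CI.

    A 0.5 continuity correction is applied to every cell whenever any
    cell is zero.
    """
    present = np.asarray(present).astype(bool)
    labels = np.asarray(labels).astype(bool)
    a = float(np.sum(present & labels))        # present, malignant
    b = float(np.sum(present & ~labels))       # present, benign
    c = float(np.sum(~present & labels))       # absent, malignant
    d = float(np.sum(~present & ~labels))      # absent, benign
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    lo, hi = math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
    return or_, (lo, hi)


# ---------------------------------------------------------------------------
# Method comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    methods: list[str]
    fold_aucs: dict[str, np.ndarray]
    means: dict[str, float]
    sds: dict[str, float]
    tests: dict[tuple[str, str], tuple[float, float]]   # (t, p)
    paired: bool

    def to_dict(self) -> dict:
        return {
            "methods": self.methods,
            "paired": self.paired,
            "fold_aucs": {m: list(map(float, v))
                          for m, v in self.fold_aucs.items()},
            "means": self.means,
            "sds": self.sds,
            "tests": [
                {"a": a, "b": b, "t": t, "p": p}
                for (a, b), (t, p) in self.tests.items()
            ],
        }


def _ttest(
    x: np.ndarray, y: np.ndarray, paired: bool, corrected: bool = False,
    test_fraction: float = 0.0,
) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        d = x - y
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                return 0.0, 1.0
            return math.copysign(math.inf, d.mean()), 0.0
        if corrected:
            # Nadeau-Bengio variance inflation for resampled estimates
            n = d.size
            var = d.var(ddof=1) * (1 / n + test_fraction / (1 - test_fraction))
            t = d.mean() / math.sqrt(var)
            p = 2 * stats.t.sf(abs(t), df=n - 1)
            return float(t), float(p)
        res = stats.ttest_rel(x, y)
        return float(res.statistic), float(res.pvalue)
    if np.allclose(x.std(ddof=1), 0) and np.allclose(y.std(ddof=1), 0):
        if np.allclose(x.mean(), y.mean()):
            return 0.0, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    res = stats.ttest_ind(x, y)
    return float(res.statistic), float(res.pvalue)


def compare_methods(
    fold_aucs: Mapping[str, Sequence[float]],
    paired: bool = True,
    corrected: bool = False,
    test_fraction: float = 0.0,
) -> ComparisonResult:
    """Means, SDs and pairwise two-tailed t-tests over per-fold AUCs.

    Paired tests require equal fold counts (identical partitions);
    identical vectors give t = 0, p = 1.
    """
    methods = list(fold_aucs)
    if len(methods) < 2:
        raise EvaluationError("need at least two methods to compare")
    arrays = {m: np.asarray(fold_aucs[m], dtype=float) for m in methods}
    lengths = {len(v) for v in arrays.values()}
    if paired and len(lengths) != 1:
        raise EvaluationError("paired comparison requires equal fold counts")
    for m, v in arrays.items():
        if len(v) < 2:
            raise EvaluationError(f"method {m!r} has fewer than 2 folds")
    tests = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            tests[(a, b)] = _ttest(
                arrays[a], arrays[b], paired, corrected, test_fraction
            )
    return ComparisonResult(
        methods=methods,
        fold_aucs=arrays,
        means={m: float(v.mean()) for m, v in arrays.items()},
        sds={m: float(v.std(ddof=1)) for m, v in arrays.items()},
        tests=tests,
        paired=paired,
    )


# ---------------------------------------------------------------------------
# Cross-validation experiment
# ---------------------------------------------------------------------------

CV_METHODS = ("lr0", "lr1", "afm", "gafm", "max_combination", "cadx")


def _cadx_scores(dataset: EncodedDataset) -> np.ndarray:
    """Recover the per-sample CADx score column from the encoding.

    For the real-valued CADx mode the slot carries the score itself;
    for discretized modes the active level index serves as an ordinal
    surrogate score.
    """
    d = dataset.dictionary
    off = d.offset(d.cadx_feature)
    w = len(d.levels_of(d.cadx_feature))
    block = dataset.X[:, off : off + w]
    if d.cadx_rule.mode == "real":
        return block[:, 0]
    return block @ np.arange(1, w + 1)


def run_cv_experiment(
    dataset: EncodedDataset,
    methods: Sequence[str],
    k: int = 10,
    seed: int = 0,
    config: TrainingConfig | None = None,
    partition: str = "balanced",
    cadx_scores: np.ndarray | None = None,
) -> tuple[ComparisonResult, FoldAssignment]:
    """Train each method on k-1 folds and score the held-out fold.

    All methods share one partition, so the comparison is paired.
    ``afm`` and ``gafm`` share the converged step-1 fit within a fold
    (the AFM is by definition the ungated converged model; GAFM
    continues with the gate and a retrain).  ``max_combination``
    takes the per-sample maximum of the CADx score and a logistic fit
    on the non-CADx features.
    """
    for m in methods:
        if m not in CV_METHODS:
            raise EvaluationError(f"unknown method {m!r}")
    config = config or TrainingConfig(seed=seed)
    if partition == "balanced":
        folds = balanced_partition(dataset, k, seed)
    else:
        folds = stratified_partition(dataset, k, seed)
    if cadx_scores is None:
        cadx_scores = _cadx_scores(dataset)

    unique_methods = list(dict.fromkeys(methods))
    fold_aucs: dict[str, list[float]] = {m: [] for m in methods}
    y = dataset.y
    need_fm = {"afm", "gafm"} & set(unique_methods)
    need_lr = {"lr0", "lr1"} & set(unique_methods)

    for f in range(k):
        train_idx, test_idx = folds.indices(f)
        train = dataset.subset(train_idx)
        test = dataset.subset(test_idx)
        preds: dict[str, np.ndarray] = {}

        if need_fm:
            step1, _ = train_step1(train, config)
            if "afm" in unique_methods:
                preds["afm"] = forward_batch(test, step1)[1]
            if "gafm" in unique_methods:
                importance = average_attention(
                    train, step1, divisor=config.attention_average
                )
                from .gafm import init_parameters
                from .training import _restart_seed, resolve_epsilon
                gamma = apply_gate(
                    importance, resolve_epsilon(importance, config)
                )
                seed2 = _restart_seed(config, 0) + 1
                gated = replace(
                    init_parameters(
                        train.width, config.embedding_dim,
                        config.attention_hidden, seed=seed2,
                        scale=config.init_scale, use_bias=config.bias,
                    ),
                    gamma=gamma,
                )
                step2, _ = train_step2(train, config, gated)
                preds["gafm"] = forward_batch(test, step2)[1]
        if need_lr:
            lr0 = _logistic(config.seed).fit(train.X, train.y)
            if "lr0" in unique_methods:
                preds["lr0"] = lr0.predict_proba(test.X)[:, 1]
            if "lr1" in unique_methods:
                order = np.argsort(-np.abs(lr0.coef_[0]), kind="stable")
                support = np.sort(order[: min(config.top_k, train.width)])
                lr1 = _logistic(config.seed).fit(train.X[:, support], train.y)
                preds["lr1"] = lr1.predict_proba(test.X[:, support])[:, 1]
        if "max_combination" in unique_methods:
            cadx_name = dataset.dictionary.cadx_feature
            Xtr = train.drop_feature(cadx_name)
            Xte = test.drop_feature(cadx_name)
            lr_feat = _logistic(config.seed).fit(Xtr, train.y)
            preds["max_combination"] = max_combination(
                cadx_scores[test_idx], lr_feat.predict_proba(Xte)[:, 1]
            )
        if "cadx" in unique_methods:
            preds["cadx"] = cadx_scores[test_idx]

        for m in methods:
            fold_aucs[m].append(auc(preds[m], y[test_idx]))

    # duplicate method entries keep distinct keys for the comparison
    named = {}
    for i, m in enumerate(methods):
        key = m if m not in named else f"{m}#{i}"
        named[key] = fold_aucs[m] if isinstance(m, str) else fold_aucs[m]
    comparison = compare_methods(named, paired=True)
    return comparison, folds
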