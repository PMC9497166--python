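"""Gated attentional factorization machine (GAFM).

The model scores a one-hot encoded nodule ``X`` as

    logit = b + <W, X> + sum_{(i,j) in Gamma, i,j active} a(i,j) <e_i, e_j>
    p(malignant) = sigmoid(logit)

where ``e_i = V_i x_i`` embeds each active position into a k-dimensional
vector, ``a(i,j)`` is an attention score produced by a one-hidden-layer
perceptron reading the element-wise product ``e_i * e_j`` and softmax
normalized over the sample's (retained) active pairs, and ``Gamma`` is
the gate set: pairs whose dataset-average attention exceeds a threshold
epsilon.  With ``Gamma = all pairs`` (epsilon = -inf) the model is
exactly an attentional factorization machine (AFM); with ``Gamma``
empty it collapses to logistic regression on ``X``.

The scalar pairwise contribution ``<e_i, e_j>`` equals the component
sum of the element-wise product the attention network consumes, so a
single interaction tensor serves both roles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .feature_space import EncodedDataset

__all__ = [
    "GAFMParameters",
    "AttentionOutput",
    "InteractionImportance",
    "init_parameters",
    "embed",
    "pairwise_interactions",
    "attention_scores",
    "forward",
    "forward_batch",
    "average_attention",
    "apply_gate",
    "bce_loss",
    "save_checkpoint",
    "load_checkpoint",
]

PROB_CLIP = 1e-12  # probability clipping for the cross-entropy loss


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


@dataclass
class GAFMParameters:
    """All learnable state plus the gate set.

    W        : first-order weight per one-hot position
    bias     : global intercept (absorbs class imbalance; never ranked)
    V        : (width, k) embedding matrix, row i is V_i
    attn_W   : (k, hidden) attention hidden-layer weights
    attn_b   : (hidden,) attention hidden-layer bias
    attn_p   : (hidden,) projection onto the scalar attention logit
    gamma    : retained position pairs (i < j), or None meaning all
               pairs (the AFM / pre-gate regime)
    """

    W: np.ndarray
    bias: float
    V: np.ndarray
    attn_W: np.ndarray
    attn_b: np.ndarray
    attn_p: np.ndarray
    gamma: frozenset[tuple[int, int]] | None = None
    use_bias: bool = True

    @property
    def width(self) -> int:
        return self.W.shape[0]

    @property
    def k(self) -> int:
        return self.V.shape[1]

    @property
    def hidden(self) -> int:
        return self.attn_b.shape[0]

    def __post_init__(self) -> None:
        if self.V.shape[0] != self.W.shape[0]:
            raise ValueError("V and W disagree on dictionary width")
        if self.V.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")
        if self.attn_W.shape != (self.k, self.hidden):
            raise ValueError("attention weight shape mismatch")
        if self.gamma is not None:
            for i, j in self.gamma:
                if not (0 <= i < j < self.width):
                    raise ValueError(f"invalid gate pair ({i}, {j})")

    def copy(self) -> "GAFMParameters":
        return GAFMParameters(
            W=self.W.copy(), bias=float(self.bias), V=self.V.copy(),
            attn_W=self.attn_W.copy(), attn_b=self.attn_b.copy(),
            attn_p=self.attn_p.copy(), gamma=self.gamma,
            use_bias=self.use_bias,
        )

    def gamma_matrix(self) -> np.ndarray | None:
        """Dense boolean lookup G[i, j] for position pairs in the gate."""
        if self.gamma is None:
            return None
        G = np.zeros((self.width, self.width), dtype=bool)
        for i, j in self.gamma:
            G[i, j] = True
            G[j, i] = True
        return G


def init_parameters(
    width: int,
    k: int = 8,
    hidden: int = 8,
    seed: int = 0,
    scale: float = 0.01,
    use_bias: bool = True,
) -> GAFMParameters:
    """Seeded Normal(0, scale) initialization of all trainable arrays."""
    rng = np.random.default_rng(seed)
    return GAFMParameters(
        W=rng.normal(0.0, scale, width),
        bias=0.0,
        V=rng.normal(0.0, scale, (width, k)),
        attn_W=rng.normal(0.0, scale, (k, hidden)),
        attn_b=np.zeros(hidden),
        attn_p=rng.normal(0.0, scale, hidden),
        gamma=None,
        use_bias=use_bias,
    )


# ---------------------------------------------------------------------------
# Per-sample reference operations (clear loops; the batch path is tested
# against these)
# ---------------------------------------------------------------------------

def embed(
    sample: np.ndarray, params: GAFMParameters
) -> list[tuple[int, np.ndarray]]:
    """Embeddings ``e_i = V_i x_i`` of a row's non-zero positions.

    Returns (position, vector) pairs in position order.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (params.width,):
        raise ValueError(
            f"sample width {sample.shape} does not match model width "
            f"{params.width}"
        )
    return [
        (int(i), params.V[i] * sample[i]) for i in np.flatnonzero(sample)
    ]


def pairwise_interactions(
    embeddings: Sequence[tuple[int, np.ndarray]]
) -> list[tuple[tuple[int, int], np.ndarray]]:
    """All n(n-1)/2 element-wise products e_i * e_j over distinct pairs."""
    out = []
    for a in range(len(embeddings)):
        for b in range(a + 1, len(embeddings)):
            (i, ei), (j, ej) = embeddings[a], embeddings[b]
            out.append(((i, j), ei * ej))
    return out


def _attention_logit(t: np.ndarray, params: GAFMParameters) -> float:
    h = np.maximum(params.attn_W.T @ t + params.attn_b, 0.0)
    return float(params.attn_p @ h)


@dataclass
class AttentionOutput:
    """Per-sample attention over its active (retained) pairs."""

    pairs: list[tuple[int, int]]
    raw: np.ndarray
    normalized: np.ndarray


def attention_scores(
    interactions: Sequence[tuple[tuple[int, int], np.ndarray]],
    params: GAFMParameters,
) -> AttentionOutput:
    """MLP attention logits, softmax-normalized over the given pairs."""
    pairs = [p for p, _ in interactions]
    raw = np.array([_attention_logit(t, params) for _, t in interactions])
    if raw.size == 0:
        return AttentionOutput(pairs=[], raw=raw, normalized=raw)
    z = raw - raw.max()
    ez = np.exp(z)
    return AttentionOutput(pairs=pairs, raw=raw, normalized=ez / ez.sum())


def forward(
    sample: np.ndarray, params: GAFMParameters
) -> tuple[float, float]:
    """(logit, probability) for one encoded row.

    The pairwise sum runs over active pairs retained by the gate; the
    attention softmax is taken over those same pairs.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (params.width,):
        raise ValueError("sample width does not match model width")
    emb = embed(sample, params)
    inter = pairwise_interactions(emb)
    if params.gamma is not None:
        inter = [(p, t) for p, t in inter if p in params.gamma]
    logit = (params.bias if params.use_bias else 0.0) + float(
        params.W @ sample
    )
    if inter:
        att = attention_scores(inter, params)
        for a, (_, t) in zip(att.normalized, inter):
            logit += float(a * t.sum())
    return logit, float(sigmoid(logit))


def bce_loss(probability: float | np.ndarray, label: float | np.ndarray) -> float:
    """Cross-entropy -y log p - (1-y) log(1-p), probability clipped."""
    p = np.clip(probability, PROB_CLIP, 1.0 - PROB_CLIP)
    y = np.asarray(label, dtype=float)
    return float(np.mean(-y * np.log(p) - (1.0 - y) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# Vectorized batch path
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=8)
def _pair_index(F: int):
    """Cached upper-triangle pair slots and slot->pair incidence maps."""
    iu, ju = np.triu_indices(F, 1)
    P = iu.shape[0]
    inc_i = np.zeros((P, F))
    inc_j = np.zeros((P, F))
    inc_i[np.arange(P), iu] = 1.0
    inc_j[np.arange(P), ju] = 1.0
    return iu, ju, inc_i, inc_j


@dataclass
class _BatchCache:
    """Intermediates of a batch forward pass, kept for the backward pass."""

    idx: np.ndarray          # (B, F) padded active positions
    val: np.ndarray          # (B, F) active values (0 on padding)
    mask: np.ndarray         # (B, F)
    iu: np.ndarray           # (P,) pair first slot
    ju: np.ndarray           # (P,) pair second slot
    pair_mask: np.ndarray    # (B, P) active AND gate-retained
    E: np.ndarray            # (B, F, k)
    T: np.ndarray            # (B, P, k)
    pre: np.ndarray          # (B, P, H)
    Hh: np.ndarray           # (B, P, H)
    attn: np.ndarray         # (B, P) softmax attention, 0 on masked
    dsum: np.ndarray         # (B, P) pair inner products
    logit: np.ndarray        # (B,)
    prob: np.ndarray         # (B,)


def _batch_forward(
    dataset: EncodedDataset,
    params: GAFMParameters,
    index: np.ndarray | None = None,
) -> _BatchCache:
    idx = dataset.active_idx if index is None else dataset.active_idx[index]
    val = dataset.active_val if index is None else dataset.active_val[index]
    mask = dataset.active_mask if index is None else dataset.active_mask[index]
    X = dataset.X if index is None else dataset.X[index]
    if X.shape[1] != params.width:
        raise ValueError("dataset width does not match model width")

    B, F = idx.shape
    iu, ju, _, _ = _pair_index(F)
    E = params.V[idx] * val[..., None]
    T = E[:, iu, :] * E[:, ju, :]
    pair_mask = mask[:, iu] & mask[:, ju]
    G = params.gamma_matrix()
    if G is not None:
        pair_mask = pair_mask & G[idx[:, iu], idx[:, ju]]

    pre = T @ params.attn_W + params.attn_b
    Hh = np.maximum(pre, 0.0)
    score = Hh @ params.attn_p
    score = np.where(pair_mask, score, -np.inf)
    smax = np.max(score, axis=1, keepdims=True)
    smax = np.where(np.isfinite(smax), smax, 0.0)
    ez = np.exp(score - smax)
    ez = np.where(pair_mask, ez, 0.0)
    denom = ez.sum(axis=1, keepdims=True)
    attn = np.divide(ez, denom, out=np.zeros_like(ez), where=denom > 0)

    dsum = T.sum(axis=2)
    logit = X @ params.W + (attn * dsum).sum(axis=1)
    if params.use_bias:
        logit = logit + params.bias
    return _BatchCache(
        idx=idx, val=val, mask=mask, iu=iu, ju=ju, pair_mask=pair_mask,
        E=E, T=T, pre=pre, Hh=Hh, attn=attn, dsum=dsum,
        logit=logit, prob=sigmoid(logit),
    )


def forward_batch(
    dataset: EncodedDataset,
    params: GAFMParameters,
    index: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(logits, probabilities) for every sample (or an index subset)."""
    cache = _batch_forward(dataset, params, index)
    return cache.logit, cache.prob


def _batch_backward(
    dataset: EncodedDataset,
    params: GAFMParameters,
    cache: _BatchCache,
    y: np.ndarray,
    index: np.ndarray | None = None,
) -> dict[str, np.ndarray | float]:
    """Mean cross-entropy gradient w.r.t. every trainable array."""
    X = dataset.X if index is None else dataset.X[index]
    B = cache.logit.shape[0]
    g = (cache.prob - y) / B                      # dL/dlogit

    grads: dict[str, np.ndarray | float] = {}
    grads["bias"] = float(g.sum()) if params.use_bias else 0.0
    grads["W"] = X.T @ g

    attn, dsum = cache.attn, cache.dsum
    dd = g[:, None] * attn                        # dL/d dsum
    da = g[:, None] * dsum                        # dL/d attn
    # softmax backward (attn is 0 on masked pairs, so they drop out)
    ds = attn * (da - (attn * da).sum(axis=1, keepdims=True))

    H = params.hidden
    k = params.k
    grads["attn_p"] = ds.ravel() @ cache.Hh.reshape(-1, H)
    dpre = ds[..., None] * params.attn_p * (cache.pre > 0)
    dpre_flat = dpre.reshape(-1, H)
    grads["attn_W"] = cache.T.reshape(-1, k).T @ dpre_flat
    grads["attn_b"] = dpre_flat.sum(axis=0)

    dT = dpre @ params.attn_W.T + dd[..., None]
    F = cache.idx.shape[1]
    _, _, inc_i, inc_j = _pair_index(F)
    # scatter pair gradients back onto the F embedding slots:
    # dE[:, f] = sum_p [iu[p] == f] dT_p * E_ju[p] + [ju[p] == f] ...
    dE = np.tensordot(dT * cache.E[:, cache.ju, :], inc_i, axes=([1], [0]))
    dE += np.tensordot(dT * cache.E[:, cache.iu, :], inc_j, axes=([1], [0]))
    dE = dE.transpose(0, 2, 1)          # (B, F, k)
    contrib = (dE * cache.val[..., None]).reshape(-1, k)
    flat = cache.idx.ravel()
    dV = np.stack([
        np.bincount(flat, weights=contrib[:, j], minlength=params.width)
        for j in range(k)
    ], axis=1)
    grads["V"] = dV
    return grads


# ---------------------------------------------------------------------------
# Dataset-average attention, gate
# ---------------------------------------------------------------------------

@dataclass
class InteractionImportance:
    """Dataset-average attention per co-active position pair.

    ``mean[(i, j)]`` is the average of a(i,j) over the samples that
    contributed (the co-active samples by default, or all N samples
    when built with ``divisor="total"``); ``count[(i, j)]`` is the
    number of co-active samples.
    """

    mean: dict[tuple[int, int], float]
    count: dict[tuple[int, int], int]
    n_samples: int
    divisor: str = "coactive"

    def items(self):
        return self.mean.items()


def average_attention(
    dataset: EncodedDataset,
    params: GAFMParameters,
    divisor: str = "coactive",
) -> InteractionImportance:
    """Mean attention a(i,j) per position pair over the dataset.

    Pairs never co-active are absent from the result.  ``divisor``
    selects the denominator: the pair's co-active sample count
    (default) or the total sample count N.
    """
    if divisor not in ("coactive", "total"):
        raise ValueError("divisor must be 'coactive' or 'total'")
    if dataset.n_samples == 0:
        raise ValueError("empty dataset")
    cache = _batch_forward(dataset, params)
    width = params.width
    sums = np.zeros((width, width))
    counts = np.zeros((width, width), dtype=np.int64)
    pi = cache.idx[:, cache.iu]
    pj = cache.idx[:, cache.ju]
    m = cache.pair_mask
    np.add.at(sums, (pi[m], pj[m]), cache.attn[m])
    np.add.at(counts, (pi[m], pj[m]), 1)
    ii, jj = np.nonzero(counts)
    denom = counts[ii, jj] if divisor == "coactive" else dataset.n_samples
    mean = sums[ii, jj] / denom
    return InteractionImportance(
        mean={(int(a), int(b)): float(v) for a, b, v in zip(ii, jj, mean)},
        count={(int(a), int(b)): int(c) for a, b, c in
               zip(ii, jj, counts[ii, jj])},
        n_samples=dataset.n_samples,
        divisor=divisor,
    )


def apply_gate(
    importance: InteractionImportance, epsilon: float
) -> frozenset[tuple[int, int]]:
    """Gate set Gamma = {(i,j) : mean attention > epsilon}.

    ``epsilon = -inf`` retains every co-active pair (AFM regime); an
    epsilon above every mean empties the gate, collapsing the model to
    first order.
    """
    if not (math.isfinite(epsilon) or epsilon == -math.inf):
        raise ValueError("epsilon must be finite or -inf")
    return frozenset(p for p, a in importance.mean.items() if a > epsilon)


# ---------------------------------------------------------------------------
# Checkpoint serialization (JSON; floats round-trip exactly via repr)
# ---------------------------------------------------------------------------

def save_checkpoint(params: GAFMParameters, path: str | Path) -> None:
    payload = {
        "W": params.W.tolist(),
        "bias": params.bias,
        "V": params.V.tolist(),
        "attn_W": params.attn_W.tolist(),
        "attn_b": params.attn_b.tolist(),
        "attn_p": params.attn_p.tolist(),
        "gamma": None if params.gamma is None
        else sorted([list(p) for p in params.gamma]),
        "use_bias": params.use_bias,
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> GAFMParameters:
    d = json.loads(Path(path).read_text())
    return GAFMParameters(
        W=np.array(d["W"], dtype=float),
        bias=float(d["bias"]),
        V=np.array(d["V"], dtype=float),
        attn_W=np.array(d["attn_W"], dtype=float),
        attn_b=np.array(d["attn_b"], dtype=float),
        attn_p=np.array(d["attn_p"], dtype=float),
        gamma=None if d["gamma"] is None
        else frozenset(tuple(p) for p in d["gamma"]),
        use_bias=bool(d["use_bias"]),
    )
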