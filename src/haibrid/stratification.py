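"""Integer scorecard and 1-5 malignancy risk stratification.

The selected features' normalized weights are scaled by an integer
multiplication factor and rounded, giving a human-readable additive
point card.  Summed points map to empirical malignancy rates
MR(score) = M(score) / (M(score) + B(score)); contiguous score ranges
[a_i, a_{i+1}) are assigned to ordered risk categories (2, 3, 4A, 4B,
4C, 5 by default) whose malignancy-rate bounds follow TIRADS
conventions, and a diagnosis threshold is chosen by maximizing F1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_space import FeatureDictionary, decode_feature_index
from .training import SelectedFeatureSet

__all__ = [
    "ScoreCard",
    "RiskTable",
    "CategoryBounds",
    "default_category_bounds",
    "integerize",
    "score_sample",
    "score_dataset",
    "malignancy_rate_table",
    "fit_category_ranges",
    "f1_optimal_threshold",
]


class StratificationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scorecard
# ---------------------------------------------------------------------------

@dataclass
class ScoreCardEntry:
    identity: int | tuple[int, int]
    name: str
    weight: float
    score: int


@dataclass
class ScoreCard:
    """Additive integer point card over selected features.

    A pair entry contributes its points only when both constituent
    levels are present in the sample (a second-order feature is the
    co-occurrence of its two levels).
    """

    entries: list[ScoreCardEntry]
    factor: int
    rank_fidelity: float
    fidelity_ok: bool
    weight_mode: str
    dictionary_spec: dict | None = None

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "rank_fidelity": self.rank_fidelity,
            "fidelity_ok": self.fidelity_ok,
            "weight_mode": self.weight_mode,
            "entries": [
                {
                    "identity": list(e.identity)
                    if isinstance(e.identity, tuple) else e.identity,
                    "name": e.name,
                    "weight": e.weight,
                    "score": e.score,
                }
                for e in self.entries
            ],
            "dictionary_spec": self.dictionary_spec,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoreCard":
        return cls(
            entries=[
                ScoreCardEntry(
                    identity=tuple(e["identity"])
                    if isinstance(e["identity"], list) else int(e["identity"]),
                    name=e["name"],
                    weight=float(e["weight"]),
                    score=int(e["score"]),
                )
                for e in d["entries"]
            ],
            factor=int(d["factor"]),
            rank_fidelity=float(d["rank_fidelity"]),
            fidelity_ok=bool(d["fidelity_ok"]),
            weight_mode=d["weight_mode"],
            dictionary_spec=d.get("dictionary_spec"),
        )

    def to_markdown(self) -> str:
        lines = [
            "| Feature | Weight | Points |",
            "|---|---|---|",
        ]
        for e in self.entries:
            lines.append(f"| {e.name} | {e.weight:.4f} | {e.score} |")
        lines.append("")
        lines.append(f"Multiplication factor: {self.factor} "
                     f"(rank fidelity {self.rank_fidelity:.4f})")
        return "\n".join(lines)


def _presence_matrix(X: np.ndarray, card: ScoreCard) -> np.ndarray:
    """(n_samples, n_entries) indicator of entry presence (co-presence
    for pairs)."""
    cols = []
    for e in card.entries:
        if isinstance(e.identity, tuple):
            i, j = e.identity
            cols.append((X[:, i] > 0) & (X[:, j] > 0))
        else:
            cols.append(X[:, e.identity] > 0)
    return np.column_stack(cols).astype(float)


def _rank_fidelity(float_scores: np.ndarray, int_scores: np.ndarray) -> float:
    """Spearman rank agreement between pre- and post-rounding scores."""
    if np.ptp(float_scores) == 0 and np.ptp(int_scores) == 0:
        return 1.0
    if np.ptp(float_scores) == 0 or np.ptp(int_scores) == 0:
        return 0.0
    rho = stats.spearmanr(float_scores, int_scores).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def integerize(
    selected: SelectedFeatureSet,
    X: np.ndarray,
    factor_range: tuple[int, int] = (1, 100),
    fidelity_threshold: float = 0.995,
    factor: int | None = None,
    dictionary: FeatureDictionary | None = None,
) -> ScoreCard:
    """Turn normalized weights into an integer point card.

    Searches integer factors in ``factor_range`` and keeps the
    smallest one whose rounded points preserve the ranking of the
    training samples' summed scores (Spearman rank correlation above
    ``fidelity_threshold``).  If none reaches the threshold the best
    factor is returned with ``fidelity_ok=False``.  Pass ``factor`` to
    override the search.
    """
    if not selected.entries:
        raise StratificationError("no selected features to integerize")
    weights = np.array([e.weight for e in selected.entries])
    card_stub = ScoreCard(
        entries=[
            ScoreCardEntry(e.identity, e.name, e.weight, 0)
            for e in selected.entries
        ],
        factor=1, rank_fidelity=0.0, fidelity_ok=False,
        weight_mode=selected.weight_mode,
        dictionary_spec=dictionary.to_spec() if dictionary else None,
    )
    P = _presence_matrix(X, card_stub)
    float_scores = P @ weights

    def fidelity(f: int) -> tuple[float, np.ndarray]:
        ints = np.rint(f * weights)
        return _rank_fidelity(float_scores, P @ ints), ints

    candidates = (
        [factor] if factor is not None
        else range(factor_range[0], factor_range[1] + 1)
    )
    best_f, best_rho, best_ints = None, -np.inf, None
    for f in candidates:
        rho, ints = fidelity(int(f))
        if rho > best_rho:
            best_f, best_rho, best_ints = int(f), rho, ints
        if factor is None and rho >= fidelity_threshold:
            best_f, best_rho, best_ints = int(f), rho, ints
            break
    for entry, s in zip(card_stub.entries, best_ints):
        entry.score = int(s)
    card_stub.factor = best_f
    card_stub.rank_fidelity = float(best_rho)
    card_stub.fidelity_ok = best_rho >= fidelity_threshold
    return card_stub


def score_sample(
    present: set | Sequence, card: ScoreCard
) -> int:
    """Summed integer score of one sample.

    ``present`` is the set of active one-hot positions.  Single
    entries count when their position is present; pair entries when
    both members are present; absent entries contribute 0.
    """
    present = set(present)
    total = 0
    for e in card.entries:
        if isinstance(e.identity, tuple):
            if e.identity[0] in present and e.identity[1] in present:
                total += e.score
        elif e.identity in present:
            total += e.score
    return total


def score_dataset(X: np.ndarray, card: ScoreCard) -> np.ndarray:
    """Summed integer scores for every row of a design matrix."""
    ints = np.array([e.score for e in card.entries])
    return (_presence_matrix(X, card) @ ints).astype(int)


# ---------------------------------------------------------------------------
# Malignancy-rate table and category ranges
# ---------------------------------------------------------------------------

def malignancy_rate_table(
    scores: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Per-score counts and malignancy rate MR = M / (M + B)."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise StratificationError("need at least one sample")
    df = pd.DataFrame({"score": scores, "label": labels})
    g = df.groupby("score")["label"]
    table = pd.DataFrame({
        "score": g.size().index,
        "malignant": g.sum().to_numpy(),
        "benign": (g.size() - g.sum()).to_numpy(),
    })
    table["n"] = table["malignant"] + table["benign"]
    table["malignancy_rate"] = table["malignant"] / table["n"]
    return table.reset_index(drop=True)


def merge_sparse_scores(
    table: pd.DataFrame, min_count: int = 5
) -> pd.DataFrame:
    """Merge scores with fewer than ``min_count`` samples into the
    nearest neighbouring score (rate estimates are unstable at tiny
    denominators).  The merged row keeps the receiving score value."""
    rows = table.sort_values("score").to_dict("records")
    changed = True
    while changed and len(rows) > 1:
        changed = False
        for idx, row in enumerate(rows):
            if row["n"] >= min_count:
                continue
            if idx == 0:
                nb = 1
            elif idx == len(rows) - 1:
                nb = idx - 1
            else:
                d_lo = row["score"] - rows[idx - 1]["score"]
                d_hi = rows[idx + 1]["score"] - row["score"]
                nb = idx - 1 if d_lo <= d_hi else idx + 1
            rows[nb]["malignant"] += row["malignant"]
            rows[nb]["benign"] += row["benign"]
            rows[nb]["n"] += row["n"]
            rows[nb]["member_scores"] = sorted(
                set(rows[nb].get("member_scores", [rows[nb]["score"]]))
                | set(row.get("member_scores", [row["score"]]))
            )
            del rows[idx]
            changed = True
            break
    out = pd.DataFrame(rows)
    if "member_scores" not in out.columns:
        out["member_scores"] = [[s] for s in out["score"]]
    else:
        out["member_scores"] = [
            ms if isinstance(ms, list) else [s]
            for ms, s in zip(out["member_scores"], out["score"])
        ]
    out["malignancy_rate"] = out["malignant"] / out["n"]
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class CategoryBound:
    name: str
    lo: float
    hi: float  # half-open [lo, hi) unless degenerate lo == hi (exact)

    def contains(self, rate: float, last: bool = False) -> bool:
        if self.lo == self.hi:
            return rate == self.lo
        if last:
            return self.lo <= rate <= self.hi
        return self.lo <= rate < self.hi


@dataclass
class CategoryBounds:
    bounds: list[CategoryBound]

    def __post_init__(self) -> None:
        for a, b in zip(self.bounds, self.bounds[1:]):
            if b.lo < a.hi or (a.lo == a.hi and b.lo == a.hi and b.lo == b.hi):
                raise StratificationError(
                    f"category bounds {a.name} and {b.name} overlap"
                )
        for b in self.bounds:
            if not (0 <= b.lo <= b.hi <= 1):
                raise StratificationError(
                    f"category {b.name} bounds outside [0, 1]"
                )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Sequence[float]]):
        return cls([
            CategoryBound(name, float(lo), float(hi))
            for name, (lo, hi) in mapping.items()
        ])


def default_category_bounds() -> CategoryBounds:
    """TIRADS-convention malignancy-rate intervals per category.

    Category 2 is exactly-benign (rate 0); 3 under 5%; 4A 5-10%;
    4B 10-50%; 4C 50-90%; 5 above 90%.  Category 1 (normal gland, no
    nodule) has no score range by construction.
    """
    return CategoryBounds.from_mapping({
        "2": (0.0, 0.0),
        "3": (0.0, 0.05),
        "4A": (0.05, 0.10),
        "4B": (0.10, 0.50),
        "4C": (0.50, 0.90),
        "5": (0.90, 1.0),
    })


@dataclass
class RiskCategory:
    name: str
    rate_lo: float
    rate_hi: float
    score_lo: int | None       # inclusive; None when the category is empty
    score_hi: int | None       # exclusive
    n: int = 0
    malignant: int = 0

    @property
    def empirical_rate(self) -> float | None:
        return self.malignant / self.n if self.n else None


@dataclass
class RiskTable:
    """Score ranges [a_i, a_{i+1}) per ordered risk category."""

    categories: list[RiskCategory]
    mr_table: pd.DataFrame
    threshold: int | None = None

    def category_of(self, score: int) -> str:
        for cat in self.categories:
            if cat.score_lo is None:
                continue
            if cat.score_lo <= score < cat.score_hi:
                return cat.name
        # scores outside the observed domain clamp to the edge category
        occupied = [c for c in self.categories if c.score_lo is not None]
        if score < occupied[0].score_lo:
            return occupied[0].name
        return occupied[-1].name

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "categories": [
                {
                    "name": c.name,
                    "rate_bounds": [c.rate_lo, c.rate_hi],
                    "score_range": None if c.score_lo is None
                    else [c.score_lo, c.score_hi],
                    "n": c.n,
                    "malignant": c.malignant,
                    "empirical_rate": c.empirical_rate,
                }
                for c in self.categories
            ],
            "mr_table": self.mr_table.drop(
                columns=["member_scores"], errors="ignore"
            ).to_dict("records"),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RiskTable":
        cats = [
            RiskCategory(
                name=c["name"],
                rate_lo=c["rate_bounds"][0], rate_hi=c["rate_bounds"][1],
                score_lo=None if c["score_range"] is None
                else int(c["score_range"][0]),
                score_hi=None if c["score_range"] is None
                else int(c["score_range"][1]),
                n=int(c["n"]), malignant=int(c["malignant"]),
            )
            for c in d["categories"]
        ]
        return cls(
            categories=cats,
            mr_table=pd.DataFrame(d["mr_table"]),
            threshold=d.get("threshold"),
        )

    def to_markdown(self) -> str:
        lines = [
            "| Category | Score range | Target rate | Cases | Observed rate |",
            "|---|---|---|---|---|",
        ]
        for c in self.categories:
            rng = ("-" if c.score_lo is None
                   else f"[{c.score_lo}, {c.score_hi})")
            obs = "-" if c.empirical_rate is None else f"{c.empirical_rate:.4f}"
            lines.append(
                f"| {c.name} | {rng} | [{c.rate_lo:.2f}, {c.rate_hi:.2f}] "
                f"| {c.n} | {obs} |"
            )
        if self.threshold is not None:
            lines += ["", f"Diagnosis threshold: score > {self.threshold} "
                      "is suspicious for malignancy"]
        return "\n".join(lines)


def fit_category_ranges(
    mr_table: pd.DataFrame,
    bounds: CategoryBounds | None = None,
    min_count: int = 5,
) -> RiskTable:
    """Assign contiguous score ranges to risk categories.

    A greedy left-to-right scan over ascending (sparse-merged) scores
    extends each category's range while the cumulative malignancy rate
    of the scores taken so far stays within the category's bounds.
    Categories may end up empty; every observed score must land in
    exactly one category, otherwise the malignancy rates are too
    non-monotone for the given bounds and an error is raised.
    """
    bounds = bounds or default_category_bounds()
    merged = merge_sparse_scores(mr_table, min_count=min_count)
    rows = merged.sort_values("score").to_dict("records")
    n_rows = len(rows)
    cats: list[RiskCategory] = []
    r = 0
    for b_idx, b in enumerate(bounds.bounds):
        last = b_idx == len(bounds.bounds) - 1
        start = r
        cum_m = cum_n = 0
        while r < n_rows:
            m = cum_m + rows[r]["malignant"]
            n = cum_n + rows[r]["n"]
            if b.contains(m / n, last=last):
                cum_m, cum_n = m, n
                r += 1
            else:
                break
        if r > start:
            member = sorted(
                s for row in rows[start:r] for s in row["member_scores"]
            )
            hi = (max(member) + 1 if r == n_rows
                  else min(s for s in rows[r]["member_scores"]))
            cats.append(RiskCategory(
                name=b.name, rate_lo=b.lo, rate_hi=b.hi,
                score_lo=int(min(member)), score_hi=int(hi),
                n=int(cum_n), malignant=int(cum_m),
            ))
        else:
            cats.append(RiskCategory(
                name=b.name, rate_lo=b.lo, rate_hi=b.hi,
                score_lo=None, score_hi=None,
            ))
    if r < n_rows:
        raise StratificationError(
            "malignancy rates are too non-monotone for the category "
            "bounds; widen the bounds or increase score merging"
        )
    occupied = [c.empirical_rate for c in cats if c.n > 0]
    if any(b > a + 1e-12 for a, b in zip(occupied[1:], occupied)):
        raise StratificationError(
            "empirical category malignancy rates are not non-decreasing"
        )
    return RiskTable(categories=cats, mr_table=merged)


# ---------------------------------------------------------------------------
# F1-optimal diagnosis threshold
# ---------------------------------------------------------------------------

def f1_optimal_threshold(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[int, float]:
    """Integer threshold t maximizing F1 of "score > t => malignant".

    Exhaustive scan over every candidate cut (below the minimum and at
    each observed score); ties resolve to the smallest t.  Returns
    (threshold, best F1).
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise StratificationError("both classes required to tune a threshold")
    candidates = np.unique(scores)
    candidates = np.concatenate(([candidates[0] - 1], candidates))
    best_t, best_f1 = None, -1.0
    for t in candidates:
        pred = scores > t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        if f1 > best_f1:
            best_t, best_f1 = int(t), f1
    return best_t, best_f1
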