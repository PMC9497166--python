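"""Candidate feature space: dictionary, one-hot encoding, decoding.

Per-nodule records carry categorical ultrasonographic descriptors (a
TIRADS-style lexicon), an optional continuous CADx malignancy score in
[0, 1] produced by an image model, and a binary pathology label.  Each
categorical feature is one-hot encoded into a block of positions; an
absent descriptor encodes as an all-zero block.  The CADx score enters
the candidate set as one more feature, by default binarized at a
threshold into a two-level "CADx diagnosis" pseudo-feature, optionally
quantile-binned or kept as a single real-valued slot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CadxRule",
    "FeatureDictionary",
    "EncodedDataset",
    "build_dictionary",
    "default_dictionary_spec",
    "default_dictionary",
    "load_dictionary",
    "encode",
    "decode_feature_index",
]

LABEL_COLUMN = "label"
CADX_SCORE_COLUMN = "cadx_score"


class DictionaryError(ValueError):
    """Invalid feature-dictionary specification."""


class EncodingError(ValueError):
    """A record cannot be encoded against the dictionary."""


@dataclass(frozen=True)
class CadxRule:
    """How the continuous CADx score maps onto its feature block.

    mode:
        ``"binary"``  -- one of two levels, split at ``threshold``;
        ``"quantile"``-- ``bins`` levels split at score quantiles
                         computed on the data being encoded;
        ``"real"``    -- a single slot whose value is the raw score.
    """

    mode: str = "binary"
    threshold: float = 0.5
    bins: int = 4

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "quantile", "real"):
            raise DictionaryError(f"unknown CADx mode {self.mode!r}")
        if self.mode == "binary" and not (0.0 <= self.threshold <= 1.0):
            raise DictionaryError("CADx threshold must lie in [0, 1]")
        if self.mode == "quantile" and self.bins < 2:
            raise DictionaryError("quantile CADx discretization needs >= 2 bins")

    def levels(self) -> tuple[str, ...]:
        if self.mode == "binary":
            return ("benign", "malignant")
        if self.mode == "quantile":
            return tuple(f"q{i + 1}" for i in range(self.bins))
        return ("score",)


@dataclass(frozen=True)
class FeatureDictionary:
    """Ordered catalogue of categorical features and their levels.

    Positions are assigned feature-by-feature in specification order,
    levels in specification order, so the one-hot layout is stable
    across runs.  Exactly one feature is the CADx-diagnosis
    pseudo-feature.
    """

    features: tuple[tuple[str, tuple[str, ...]], ...]
    cadx_feature: str
    cadx_rule: CadxRule = field(default_factory=CadxRule)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.features]
        if len(names) < 2:
            raise DictionaryError("dictionary needs at least 2 features")
        if len(set(names)) != len(names):
            raise DictionaryError("duplicate feature names in dictionary")
        for name, levels in self.features:
            if len(levels) < 1:
                raise DictionaryError(f"feature {name!r} has no levels")
            if name != self.cadx_feature and len(levels) < 2:
                raise DictionaryError(f"feature {name!r} needs >= 2 levels")
            if len(set(levels)) != len(levels):
                raise DictionaryError(f"duplicate level names in feature {name!r}")
        if self.cadx_feature not in names:
            raise DictionaryError(
                f"CADx feature {self.cadx_feature!r} not in dictionary"
            )

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.features)

    @property
    def total_width(self) -> int:
        return sum(len(levels) for _, levels in self.features)

    def offset(self, feature: str) -> int:
        off = 0
        for name, levels in self.features:
            if name == feature:
                return off
            off += len(levels)
        raise KeyError(feature)

    def levels_of(self, feature: str) -> tuple[str, ...]:
        for name, levels in self.features:
            if name == feature:
                return levels
        raise KeyError(feature)

    def position(self, feature: str, level: str) -> int:
        levels = self.levels_of(feature)
        try:
            return self.offset(feature) + levels.index(level)
        except ValueError:
            raise EncodingError(
                f"unknown level {level!r} for feature {feature!r}"
            ) from None

    def to_spec(self) -> dict:
        return {
            "features": [
                {"name": name, "levels": list(levels)}
                for name, levels in self.features
                if name != self.cadx_feature
            ],
            "cadx": {
                "name": self.cadx_feature,
                "mode": self.cadx_rule.mode,
                "threshold": self.cadx_rule.threshold,
                "bins": self.cadx_rule.bins,
            },
        }


def default_dictionary_spec() -> dict:
    """Shipped TIRADS+-style candidate feature specification.

    Covers the Kwak-style grey-scale families (composition,
    echogenicity, margin, shape, echogenic foci) plus colour-Doppler
    vascularity localization (five patterns) and morphology
    (twisted/untwisted), halo presence and thickness, posterior
    acoustic features, echo-texture heterogeneity, and the CADx
    diagnosis pseudo-feature.
    """
    return {
        "features": [
            {"name": "composition",
             "levels": ["cystic", "spongiform", "mixed", "solid"]},
            {"name": "echogenicity",
             "levels": ["anechoic", "hyperechoic", "isoechoic",
                        "hypoechoic", "marked-hypoechoic"]},
            {"name": "margin",
             "levels": ["smooth", "ill-defined", "irregular",
                        "extrathyroidal-extension"]},
            {"name": "shape",
             "levels": ["wider-than-tall", "taller-than-wide"]},
            {"name": "echogenic_foci",
             "levels": ["none", "comet-tail", "macrocalcification",
                        "rim-calcification", "punctate"]},
            {"name": "vascular_localization",
             "levels": ["absent", "perinodular", "peripheral",
                        "mixed", "central"]},
            {"name": "vascular_morphology",
             "levels": ["untwisted", "twisted"]},
            {"name": "halo",
             "levels": ["absent", "thin", "thick"]},
            {"name": "posterior_features",
             "levels": ["none", "enhancement", "shadowing", "combined"]},
            {"name": "echo_texture",
             "levels": ["homogeneous", "heterogeneous"]},
        ],
        "cadx": {"name": "cadx_diagnosis", "mode": "binary",
                 "threshold": 0.5, "bins": 4},
    }


def build_dictionary(spec: Mapping) -> FeatureDictionary:
    """Validate a dictionary specification and assign positions.

    The specification is a mapping with a ``features`` list of
    ``{"name", "levels"}`` entries and a ``cadx`` mapping naming the
    CADx pseudo-feature and its discretization rule.  Positions follow
    specification order; the CADx block is appended last.
    """
    if "features" not in spec:
        raise DictionaryError("specification lacks a 'features' list")
    cadx_spec = dict(spec.get("cadx") or {})
    rule = CadxRule(
        mode=cadx_spec.get("mode", "binary"),
        threshold=float(cadx_spec.get("threshold", 0.5)),
        bins=int(cadx_spec.get("bins", 4)),
    )
    cadx_name = cadx_spec.get("name", "cadx_diagnosis")
    features = [
        (entry["name"], tuple(entry["levels"])) for entry in spec["features"]
    ]
    features.append((cadx_name, rule.levels()))
    return FeatureDictionary(
        features=tuple(features), cadx_feature=cadx_name, cadx_rule=rule
    )


def default_dictionary() -> FeatureDictionary:
    return build_dictionary(default_dictionary_spec())


def load_dictionary(path: str | Path) -> FeatureDictionary:
    """Load a dictionary specification from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        spec = yaml.safe_load(text)
    else:
        spec = json.loads(text)
    return build_dictionary(spec)


@dataclass
class EncodedDataset:
    """One-hot encoded samples with the sparse active-index view.

    ``X`` is the dense sample-by-width design matrix (binary except for
    a real-valued CADx slot).  ``active_idx``/``active_val``/
    ``active_mask`` give the padded per-sample non-zero positions and
    values the factorization machine operates on.
    """

    X: np.ndarray
    y: np.ndarray | None
    active_idx: np.ndarray
    active_val: np.ndarray
    active_mask: np.ndarray
    dictionary: FeatureDictionary

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def __post_init__(self) -> None:
        if self.X.shape[0] == 0:
            raise EncodingError("dataset must contain at least one sample")
        if self.X.shape[1] != self.dictionary.total_width:
            raise EncodingError("row width does not match dictionary width")
        if self.y is not None and not np.isin(self.y, (0, 1)).all():
            raise EncodingError("labels must be binary")

    def subset(self, index: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            X=self.X[index],
            y=None if self.y is None else self.y[index],
            active_idx=self.active_idx[index],
            active_val=self.active_val[index],
            active_mask=self.active_mask[index],
            dictionary=self.dictionary,
        )

    def drop_feature(self, feature: str) -> np.ndarray:
        """Dense design matrix with one feature's block removed."""
        off = self.dictionary.offset(feature)
        w = len(self.dictionary.levels_of(feature))
        keep = np.r_[0:off, off + w : self.width]
        return self.X[:, keep]


def _is_absent(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return isinstance(value, str) and value.strip() == ""


def _cadx_level(score: float, rule: CadxRule, edges: np.ndarray | None) -> int:
    if rule.mode == "binary":
        return 1 if score >= rule.threshold else 0
    # quantile: edges are interior quantile cut points computed on the data
    return int(np.searchsorted(edges, score, side="right"))


def encode(
    records: pd.DataFrame | Iterable[Mapping],
    dictionary: FeatureDictionary,
    require_label: bool = True,
) -> EncodedDataset:
    """Encode raw records into the one-hot design matrix.

    ``records`` is a table with one column per dictionary feature
    (string levels, empty/NaN = absent), a ``cadx_score`` column in
    [0, 1], and a binary ``label`` column (optional when
    ``require_label`` is false).  Unknown level names raise
    :class:`EncodingError` naming the record and feature.
    """
    table = pd.DataFrame(records)
    if table.shape[0] == 0:
        raise EncodingError("no records to encode")

    n = table.shape[0]
    width = dictionary.total_width
    rule = dictionary.cadx_rule
    cadx = dictionary.cadx_feature
    n_features = len(dictionary.features)

    y = None
    if LABEL_COLUMN in table.columns:
        labels = table[LABEL_COLUMN].to_numpy()
        if not np.isin(labels, (0, 1)).all():
            raise EncodingError("label column must be 0/1")
        y = labels.astype(np.int8)
    elif require_label:
        raise EncodingError(f"missing required column {LABEL_COLUMN!r}")

    scores = None
    if CADX_SCORE_COLUMN in table.columns:
        scores = table[CADX_SCORE_COLUMN].to_numpy(dtype=float)
        valid = scores[~np.isnan(scores)]
        if valid.size and (valid.min() < 0.0 or valid.max() > 1.0):
            raise EncodingError("cadx_score values must lie in [0, 1]")

    edges = None
    if rule.mode == "quantile" and scores is not None:
        qs = np.linspace(0, 1, rule.bins + 1)[1:-1]
        edges = np.quantile(scores[~np.isnan(scores)], qs)

    X = np.zeros((n, width))
    active_idx = np.zeros((n, n_features), dtype=np.int64)
    active_val = np.zeros((n, n_features))
    active_mask = np.zeros((n, n_features), dtype=bool)

    for f_pos, (name, levels) in enumerate(dictionary.features):
        off = dictionary.offset(name)
        if name == cadx:
            if scores is None:
                continue
            for i, s in enumerate(scores):
                if np.isnan(s):
                    continue
                if rule.mode == "real":
                    pos, val = off, float(s)
                else:
                    pos, val = off + _cadx_level(float(s), rule, edges), 1.0
                X[i, pos] = val
                active_idx[i, f_pos] = pos
                active_val[i, f_pos] = val
                active_mask[i, f_pos] = True
            continue
        if name not in table.columns:
            continue
        col = table[name]
        level_index = {lv: k for k, lv in enumerate(levels)}
        for i, value in enumerate(col):
            if _is_absent(value):
                continue
            try:
                k = level_index[value]
            except KeyError:
                raise EncodingError(
                    f"record {i}: unknown level {value!r} for feature {name!r}"
                ) from None
            pos = off + k
            X[i, pos] = 1.0
            active_idx[i, f_pos] = pos
            active_val[i, f_pos] = 1.0
            active_mask[i, f_pos] = True

    return EncodedDataset(
        X=X, y=y, active_idx=active_idx, active_val=active_val,
        active_mask=active_mask, dictionary=dictionary,
    )


def decode_feature_index(
    index: int, dictionary: FeatureDictionary
) -> tuple[str, str]:
    """Map a one-hot position back to its (feature, level) pair."""
    if not 0 <= index < dictionary.total_width:
        raise IndexError(
            f"position {index} out of range for width {dictionary.total_width}"
        )
    off = 0
    for name, levels in dictionary.features:
        if index < off + len(levels):
            return name, levels[index - off]
        off += len(levels)
    raise AssertionError("unreachable")


def decode_identity(
    identity: int | tuple[int, int], dictionary: FeatureDictionary
) -> str:
    """Human-readable name for a position or a position pair."""
    if isinstance(identity, tuple):
        a = decode_feature_index(identity[0], dictionary)
        b = decode_feature_index(identity[1], dictionary)
        return f"{a[0]}={a[1]} & {b[0]}={b[1]}"
    f, l = decode_feature_index(identity, dictionary)
    return f"{f}={l}"
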