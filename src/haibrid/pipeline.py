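"""End-to-end pipeline: encode, two-step train, scorecard, risk table.

``run_pipeline`` glues the stages together — encode the records,
train the gated attentional factorization machine in two steps, rank
and select the top features, integerize their weights, build the
malignancy-rate table and category score ranges, tune the F1-optimal
diagnosis threshold, and (optionally) run the cross-validation
comparison — writing JSON and Markdown artifacts plus a run manifest.
``score_new_cases`` applies a stored scorecard and risk table to new
records without retraining.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evaluation import auc, odds_ratio, run_cv_experiment
from .feature_space import (
    EncodedDataset,
    FeatureDictionary,
    build_dictionary,
    default_dictionary,
    encode,
)
from .stratification import (
    CategoryBounds,
    RiskTable,
    ScoreCard,
    default_category_bounds,
    f1_optimal_threshold,
    fit_category_ranges,
    malignancy_rate_table,
    score_dataset,
    integerize,
)
from .synth import default_generator_spec, generate
from .training import TrainingConfig, rank_and_select, two_step_train

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
           "score_new_cases"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    data: str | Path | None = None          # CSV/TSV table; None = simulate
    dictionary: str | Path | None = None    # JSON/YAML spec; None = default
    out: str | Path = "haibrid_out"
    n_synthetic: int = 3000
    generator: str = "default"              # synthetic regime: default|hybrid
    seed: int = 0
    training: TrainingConfig | None = None
    bounds: Mapping[str, Sequence[float]] | None = None
    min_score_count: int = 5
    run_cv: bool = False
    cv_methods: tuple[str, ...] = ("gafm", "afm", "lr1", "lr0", "cadx")
    cv_folds: int = 5


@dataclass
class PipelineResult:
    scorecard: ScoreCard
    risk_table: RiskTable
    selected: object
    threshold: int
    f1: float
    train_auc: float
    comparison: object | None
    manifest: dict


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _config_hash(config: PipelineConfig, training: TrainingConfig) -> str:
    payload = json.dumps(
        {"pipeline": {k: str(v) for k, v in asdict(config).items()
                      if k != "training"},
         "training": asdict(training)},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full scorecard-construction workflow.

    With ``config.data`` unset, a synthetic cohort from the default
    generator specification is used.  Artifacts are written under
    ``config.out``: scorecard.json, risk_table.json, criteria.md,
    selected_features.json, score_distribution.csv, manifest.json and,
    when ``run_cv`` is on, cv_comparison.json.
    """
    training = config.training or TrainingConfig(seed=config.seed)
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)

    # --- load or simulate ---------------------------------------------
    if config.dictionary is not None:
        from .feature_space import load_dictionary
        if not Path(config.dictionary).exists():
            raise PipelineError(
                f"stage 'config' failed: dictionary file "
                f"{config.dictionary} does not exist"
            )
        dictionary = load_dictionary(config.dictionary)
    else:
        dictionary = default_dictionary()

    if config.data is not None:
        if not Path(config.data).exists():
            raise PipelineError(
                f"stage 'config' failed: data file {config.data} "
                "does not exist"
            )
        sep = "\t" if str(config.data).endswith((".tsv", ".txt")) else ","
        table = pd.read_csv(config.data, sep=sep)
    else:
        from .synth import hybrid_generator_spec
        maker = (hybrid_generator_spec if config.generator == "hybrid"
                 else default_generator_spec)
        spec = maker(n=config.n_synthetic, seed=config.seed)
        if config.dictionary is None:
            dictionary = spec.dictionary
        table, _ = generate(spec)

    # --- encode -------------------------------------------------------
    dataset = _stage("encode")(encode)(table, dictionary)

    # --- two-step training -------------------------------------------
    result = _stage("train")(two_step_train)(dataset, training)

    # --- rank and select ---------------------------------------------
    selected = _stage("select")(rank_and_select)(
        result.params, result.importance, training, dictionary,
        coefficients=result.coefficients,
    )

    # --- integerize ---------------------------------------------------
    card = _stage("integerize")(integerize)(
        selected, dataset.X, dictionary=dictionary
    )

    # --- malignancy rates, ranges, threshold -------------------------
    scores = score_dataset(dataset.X, card)
    mr = _stage("malignancy_rates")(malignancy_rate_table)(scores, dataset.y)
    bounds = (CategoryBounds.from_mapping(config.bounds)
              if config.bounds else default_category_bounds())
    risk = _stage("category_ranges")(fit_category_ranges)(
        mr, bounds, min_count=config.min_score_count
    )
    threshold, f1 = _stage("threshold")(f1_optimal_threshold)(
        scores, dataset.y
    )
    risk.threshold = threshold
    train_auc = auc(scores, dataset.y)

    # --- optional cross-validation comparison ------------------------
    comparison = None
    if config.run_cv:
        comparison, _ = _stage("cv")(run_cv_experiment)(
            dataset, list(config.cv_methods), k=config.cv_folds,
            seed=config.seed, config=training,
            cadx_scores=table["cadx_score"].to_numpy()
            if "cadx_score" in table else None,
        )

    # --- artifacts ----------------------------------------------------
    from . import __version__
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config, training),
        "n_samples": int(dataset.n_samples),
        "dictionary_width": dictionary.total_width,
        "gate_epsilon": result.epsilon,
        "retained_pairs": sorted(map(list, result.params.gamma or [])),
        "threshold": threshold,
        "f1": f1,
        "train_auc": train_auc,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "scorecard.json").write_text(json.dumps(card.to_dict(), indent=1))
    (out / "risk_table.json").write_text(json.dumps(risk.to_dict(), indent=1))
    (out / "selected_features.json").write_text(
        json.dumps(selected.to_dict(), indent=1)
    )
    (out / "criteria.md").write_text(
        "# HAIbrid-TIRADS criteria\n\n## Scorecard\n\n"
        + card.to_markdown()
        + "\n\n## Risk stratification\n\n"
        + risk.to_markdown() + "\n"
    )
    dist = pd.DataFrame({"score": scores, "label": dataset.y})
    dist.groupby(["score", "label"]).size().rename("count").reset_index() \
        .to_csv(out / "score_distribution.csv", index=False)
    if comparison is not None:
        (out / "cv_comparison.json").write_text(
            json.dumps(comparison.to_dict(), indent=1)
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PipelineResult(
        scorecard=card, risk_table=risk, selected=selected,
        threshold=threshold, f1=f1, train_auc=train_auc,
        comparison=comparison, manifest=manifest,
    )


def score_new_cases(
    card: ScoreCard,
    risk: RiskTable,
    table: pd.DataFrame,
    dictionary: FeatureDictionary | None = None,
) -> pd.DataFrame:
    """Score records against a stored card: no retraining, pure lookup.

    Returns a frame with the summed score, risk category and the
    diagnosis from the stored threshold ("score > t" is suspicious).
    """
    if dictionary is None:
        if card.dictionary_spec is None:
            dictionary = default_dictionary()
        else:
            dictionary = build_dictionary(card.dictionary_spec)
    dataset = encode(table, dictionary, require_label=False)
    scores = score_dataset(dataset.X, card)
    out = pd.DataFrame({"score": scores})
    out["category"] = [risk.category_of(int(s)) for s in scores]
    if risk.threshold is not None:
        out["diagnosis"] = np.where(
            scores > risk.threshold, "suspicious", "likely-benign"
        )
    return out
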