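"""The modelling-round protocol: evaluate, merge or remove, rebuild.

A *modelling round* trains one model per technique and mount, evaluates
it on the held-out split, and then revises the behaviour class set:
behaviours the model cannot find (zero true positives, or sensitivity
below a threshold) are merged into the class they are most often
confused with when that class shares their ethogram category, and
removed from the dataset when it does not. The loop stops when neither
the overall accuracy nor the kappa improves, or when only the three
behavioural categories (active, inactive, maintenance) remain.

Two modes are provided. *Fixed-plan* mode executes a given ordered list
of :class:`RoundPlan` objects — :func:`study_round_plans` returns the
four rounds of the original cat study (15 behaviours, then 8 after the
small-sample removals and the trotting/walking merge, then 6 after
scratching joins grooming, then the 3 categories with a tighter class
cap). *Auto* mode derives each plan from the previous round's confusion
matrix via :func:`propose_round_plan`.

Class-size caps guard against over-fitting to abundant behaviours:
classes are capped at 7000 datapoints per round, tightened to 5000 in
the final three-category round. Each round re-applies its composed
mapping to the full preprocessed dataset and caps afresh, so merging
never loses datapoints, while rows of removed behaviours never return.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import models as _models
from .evaluation import (
    ClassMetrics,
    ConfusionMatrix,
    KappaResult,
    class_metrics,
    cohen_kappa,
    confusion_matrix,
    overall_accuracy,
)
from .ingestion import (
    Ethogram,
    cap_class_counts,
    default_ethogram,
    train_test_split_stratified,
)

logger = logging.getLogger(__name__)

#: Sentinel mapping target meaning "drop this behaviour's datapoints".
REMOVED = "REMOVED"

#: The 15 behaviour classes entering the first modelling round after
#: preprocessing (unobserved / rare behaviours dropped, jumping variants
#: merged, bookkeeping labels removed).
ROUND1_CLASSES: tuple[str, ...] = (
    "climbing", "jumping", "rubbing", "trotting", "walking",
    "lying", "sitting", "standing",
    "grooming", "littering", "digging", "eating", "scratching", "shaking",
    "allogrooming",
)

DEFAULT_CAP = 7000
FINAL_ROUND_CAP = 5000

CATEGORY_COLLAPSE: dict[str, str] = {
    "active": "active",
    "lying": "inactive", "sitting": "inactive", "standing": "inactive",
    "grooming": "maintenance", "eating": "maintenance",
}


@dataclass(frozen=True)
class RoundPlan:
    """Mapping of the previous round's classes to merged classes/REMOVED."""

    round_index: int
    mapping: dict[str, str]
    cap: int = DEFAULT_CAP

    def image(self) -> tuple[str, ...]:
        return tuple(sorted({t for t in self.mapping.values() if t != REMOVED}))

    def apply(self, labels: np.ndarray, unmapped: str = "remove") -> np.ndarray:
        """Map a label array through the plan.

        Labels outside the mapping are dropped (``unmapped="remove"``,
        returned as :data:`REMOVED`) or rejected (``"error"``); data-side
        class sets may legitimately be smaller than the plan's domain
        when rare behaviours never occurred.
        """
        out = np.empty(labels.size, dtype=object)
        unknown = set()
        for i, lab in enumerate(labels):
            try:
                out[i] = self.mapping[lab]
            except KeyError:
                unknown.add(lab)
                out[i] = REMOVED
        if unknown:
            if unmapped == "error":
                raise KeyError(f"labels outside round plan: {sorted(unknown)}")
            logger.info("round %d: dropping labels outside the plan: %s",
                        self.round_index, sorted(unknown))
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"round": self.round_index, "cap": self.cap,
             "mapping": dict(sorted(self.mapping.items()))},
            sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "RoundPlan":
        payload = yaml.safe_load(text)
        return cls(int(payload["round"]), dict(payload["mapping"]),
                   int(payload.get("cap", DEFAULT_CAP)))


def study_round_plans() -> list[RoundPlan]:
    """The four fixed modelling-round plans of the original cat study.

    Round 1: identity over the 15 preprocessed behaviours (cap 7000).
    Round 2: climbing, jumping, rubbing, digging, shaking and
    allogrooming removed for small sample size; trotting and walking
    merged into "active" (8 classes). Round 3: scratching merged into
    grooming and littering dropped (6 classes). Round 4: everything
    collapsed to the three behavioural categories, cap 5000.
    """
    plan1 = RoundPlan(1, {b: b for b in ROUND1_CLASSES}, DEFAULT_CAP)

    removals2 = ("climbing", "jumping", "rubbing", "digging", "shaking",
                 "allogrooming")
    mapping2 = {b: b for b in ROUND1_CLASSES}
    for b in removals2:
        mapping2[b] = REMOVED
    mapping2["trotting"] = "active"
    mapping2["walking"] = "active"
    plan2 = RoundPlan(2, mapping2, DEFAULT_CAP)

    mapping3 = {b: b for b in plan2.image()}
    mapping3["scratching"] = "grooming"
    mapping3["littering"] = REMOVED
    plan3 = RoundPlan(3, mapping3, DEFAULT_CAP)

    mapping4 = dict(CATEGORY_COLLAPSE)
    plan4 = RoundPlan(4, mapping4, FINAL_ROUND_CAP)
    return [plan1, plan2, plan3, plan4]


# Backwards-friendly alias used by the CLI ("paper mode" = fixed plans).
fixed_round_plans = study_round_plans


def compose_plans(plans: Sequence[RoundPlan]) -> dict[str, str]:
    """Total map from initial behaviours to final classes or REMOVED."""
    if not plans:
        return {}
    composed = dict(plans[0].mapping)
    for plan in plans[1:]:
        for src, mid in list(composed.items()):
            if mid == REMOVED:
                continue
            composed[src] = plan.mapping.get(mid, REMOVED)
    return composed


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the merge/remove rule and the stopping criterion."""

    low_sensitivity_threshold: float = 0.20
    require_nonzero_tp: bool = True
    improvement_epsilon: float = 0.0
    min_categories: int = 3
    cap: int = DEFAULT_CAP
    train_frac: float = 0.7
    max_rounds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_sensitivity_threshold <= 1.0:
            raise ValueError("low_sensitivity_threshold must be in [0, 1]")


def propose_round_plan(
    cm: ConfusionMatrix,
    metrics: Sequence[ClassMetrics],
    ethogram: Optional[Ethogram] = None,
    cfg: SelectionConfig = SelectionConfig(),
    round_index: int = 2,
) -> RoundPlan:
    """Derive the next round's plan from a confusion matrix.

    A class is *poorly identified* when its TP count is 0 (if
    ``require_nonzero_tp``) or its sensitivity falls below the
    threshold. Such a class is merged into the class it is most often
    confused with (largest off-diagonal row cell; ties broken toward
    the more frequent class) when that class shares its ethogram
    category, and removed otherwise. A poorly identified class that is
    never confused with anything has no merge target and is removed.
    """
    ethogram = ethogram or default_ethogram()
    by_label = {m.label: m for m in metrics}
    mapping: dict[str, str] = {}
    for i, label in enumerate(cm.classes):
        m = by_label[label]
        low = (cfg.require_nonzero_tp and m.tp == 0) or (
            m.sensitivity is not None
            and m.sensitivity < cfg.low_sensitivity_threshold)
        if not low:
            mapping[label] = label
            continue
        row = cm.counts[i].astype(float).copy()
        row[i] = -1.0
        if row.max() <= 0:
            mapping[label] = REMOVED
            continue
        best = row.max()
        candidates = [j for j in range(len(cm.classes)) if row[j] == best]
        target_j = max(candidates, key=lambda j: cm.row_sums[j])
        target = cm.classes[target_j]
        if ethogram.category(label) == ethogram.category(target):
            mapping[label] = target
        else:
            mapping[label] = REMOVED
    # resolve chains (a -> b while b itself maps to c or to REMOVED)
    for src in list(mapping):
        seen = [src]
        tgt = mapping[src]
        while tgt != REMOVED and tgt not in seen and mapping.get(tgt, tgt) != tgt:
            seen.append(tgt)
            tgt = mapping[tgt]
        if tgt in seen and tgt != src:  # merge cycle: keep the first member
            tgt = min(seen)
        mapping[src] = tgt
    return RoundPlan(round_index, mapping, cfg.cap)


@dataclass
class RoundResult:
    """Everything one modelling round produced for one technique/mount."""

    round_index: int
    technique: str
    mount: str
    model: _models.TrainedModel
    cm: ConfusionMatrix
    overall_accuracy: float
    kappa: KappaResult
    metrics: list[ClassMetrics]
    n_train: int
    n_test: int

    @property
    def classes(self) -> tuple[str, ...]:
        return self.cm.classes


def _round_seed(base_seed: int, round_index: int, salt: int) -> int:
    ss = np.random.SeedSequence((base_seed, round_index, salt))
    return int(ss.generate_state(1)[0] % (2**31))


def _train(technique: str, train_df: pd.DataFrame, seed: int,
           rf_params: Optional[_models.RFParams],
           som_params: Optional[_models.SOMParams]) -> _models.TrainedModel:
    if technique == "RF":
        params = replace(rf_params or _models.RFParams(), seed=seed)
        return _models.train_random_forest(train_df, params)
    if technique == "SOM":
        params = replace(som_params or _models.SOMParams(), seed=seed)
        return _models.train_supervised_som(train_df, params)
    raise ValueError(f"unknown technique {technique!r}; expected RF or SOM")


def _execute_round(data: pd.DataFrame, plan_mapping: dict[str, str],
                   round_index: int, cap: int, technique: str,
                   cfg: SelectionConfig,
                   rf_params, som_params) -> tuple[RoundResult, pd.DataFrame]:
    plan = RoundPlan(round_index, plan_mapping, cap)
    mapped = data.copy()
    mapped["label"] = plan.apply(mapped["label"].to_numpy(dtype=object))
    mapped = mapped[mapped["label"] != REMOVED].reset_index(drop=True)
    if mapped.empty:
        raise ValueError(f"round {round_index}: no datapoints left after the plan")
    capped = cap_class_counts(mapped, cap, _round_seed(cfg.seed, round_index, 1))
    train_df, test_df = train_test_split_stratified(
        capped, cfg.train_frac, _round_seed(cfg.seed, round_index, 2))
    model = _train(technique, train_df, _round_seed(cfg.seed, round_index, 3),
                   rf_params, som_params)
    predicted = model.predict(test_df)
    classes = tuple(sorted(set(capped["label"].tolist())))
    cm = confusion_matrix(test_df["label"].tolist(), predicted.tolist(), classes)
    result = RoundResult(
        round_index, technique, model.mount, model, cm,
        overall_accuracy(cm), cohen_kappa(cm), class_metrics(cm),
        len(train_df), len(test_df),
    )
    return result, capped


def run_modelling_rounds(
    data: pd.DataFrame,
    technique: str,
    cfg: SelectionConfig = SelectionConfig(),
    plans: Optional[Sequence[RoundPlan]] = None,
    ethogram: Optional[Ethogram] = None,
    rf_params: Optional[_models.RFParams] = None,
    som_params: Optional[_models.SOMParams] = None,
) -> list[RoundResult]:
    """Run the modelling-round protocol on one labelled dataset.

    ``data`` is a labelled feature dataset (one mount). With ``plans``
    given, each plan is composed with its predecessors, applied to the
    full dataset, capped, split, trained and evaluated — one
    :class:`RoundResult` per plan. Without ``plans``, round 1 is the
    identity and subsequent plans come from :func:`propose_round_plan`,
    stopping when the plan is the identity, when neither overall
    accuracy nor kappa improves by more than ``improvement_epsilon``,
    or when at most ``min_categories`` classes remain.
    """
    ethogram = ethogram or default_ethogram()
    base_classes = sorted(set(data["label"].tolist()))
    results: list[RoundResult] = []

    if plans is not None:
        for i, plan in enumerate(plans):
            composed = compose_plans(list(plans[: i + 1]))
            result, _ = _execute_round(
                data, composed, plan.round_index, plan.cap, technique,
                cfg, rf_params, som_params)
            results.append(result)
        return results

    identity = {b: b for b in base_classes}
    mapping = identity
    cap = cfg.cap
    prev: Optional[RoundResult] = None
    for round_index in range(1, cfg.max_rounds + 1):
        result, _ = _execute_round(data, mapping, round_index, cap,
                                   technique, cfg, rf_params, som_params)
        if prev is not None:
            gained = (result.overall_accuracy
                      > prev.overall_accuracy + cfg.improvement_epsilon
                      or (result.kappa.kappa or -1.0)
                      > (prev.kappa.kappa or -1.0) + cfg.improvement_epsilon)
            if not gained:
                results.append(result)
                break
        results.append(result)
        prev = result
        if len(result.classes) <= cfg.min_categories:
            break
        next_plan = propose_round_plan(result.cm, result.metrics, ethogram,
                                       cfg, round_index + 1)
        if all(v == k for k, v in next_plan.mapping.items()):
            break
        # compose onto the running mapping from the original label set
        mapping = {
            src: (next_plan.mapping.get(tgt, tgt) if tgt != REMOVED else REMOVED)
            for src, tgt in mapping.items()
        }
    return results


def round_report(results: Sequence[RoundResult]) -> pd.DataFrame:
    """Kappa / overall-accuracy table, one row per round x technique x mount."""
    return pd.DataFrame(
        [
            {
                "round": r.round_index,
                "mount": r.mount,
                "technique": r.technique,
                "n_classes": len(r.classes),
                "n_train": r.n_train,
                "n_test": r.n_test,
                "kappa": r.kappa.kappa,
                "overall_accuracy": r.overall_accuracy,
            }
            for r in results
        ]
    )
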