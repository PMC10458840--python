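"""End-to-end orchestration: study -> features -> rounds -> budgets.

Thin glue over the other modules so the command-line interface, the
test-suite and scripted analyses all run the identical pipeline:
annotated-window feature datasets per mount, study-level label
preprocessing (pooled across cats), and the four fixed modelling rounds
for every technique x mount combination.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import models as _models
from .features import extract_features
from .ingestion import (
    EXCLUDED_LABELS,
    Ethogram,
    FilterReport,
    LABEL_MERGES,
    MOUNTS,
    align_epochs,
    build_labeled_dataset,
    default_ethogram,
    normalise_label,
)
from .model_selection import (
    RoundResult,
    SelectionConfig,
    run_modelling_rounds,
    study_round_plans,
)
from .synthetic_data import StudyBundle

logger = logging.getLogger(__name__)

TECHNIQUES = ("RF", "SOM")


def annotated_dataset(study: StudyBundle, mount: str) -> pd.DataFrame:
    """Labelled 32-feature dataset for one mount's annotated windows.

    Synthesizes each cat's annotated-window trace, extracts per-epoch
    features, and attaches the (unfiltered) annotation labels.
    """
    frames, labels = {}, {}
    for cat in study:
        trace = cat.annotated_trace(mount)
        windows, lab = align_epochs(trace, cat.annotation)
        frames[cat.cat_id] = extract_features(trace.samples,
                                              trace.sampling_rate)
        labels[cat.cat_id] = lab
    return build_labeled_dataset(frames, labels, mount)


def preprocess_dataset(
    data: pd.DataFrame,
    min_count_s: int = 11,
    exclude_labels: Sequence[str] = EXCLUDED_LABELS,
    merges: Mapping[str, str] = LABEL_MERGES,
) -> tuple[pd.DataFrame, FilterReport]:
    """Study-level label filtering on a pooled labelled dataset.

    Applies the same rules as :func:`felacc.ingestion.preprocess_labels`
    but with behaviour counts pooled over all cats, as removal decisions
    are study-wide.
    """
    excluded = {normalise_label(l) for l in exclude_labels}
    merges = {normalise_label(k): normalise_label(v) for k, v in merges.items()}
    out = data.copy()
    raw_counts = Counter(out["label"].tolist())
    out["label"] = out["label"].map(lambda l: merges.get(l, l))
    counts = Counter(out["label"].tolist())

    report = FilterReport()
    for src, dst in merges.items():
        if raw_counts.get(src, 0):
            report.add(src, raw_counts[src], "merged", f"merged into {dst!r}")
    keep = set()
    for label, count in sorted(counts.items()):
        if label in excluded:
            report.add(label, count, "removed", "scoring bookkeeping label")
        elif count < min_count_s:
            report.add(label, count, "removed",
                       f"observed {count} s < {min_count_s} s minimum")
        else:
            keep.add(label)
            report.add(label, count, "retained", "")
    out = out[out["label"].isin(keep)].reset_index(drop=True)
    return out, report


def _combo_seed(base_seed: int, mount: str, technique: str) -> int:
    ss = np.random.SeedSequence(
        (base_seed, 7, MOUNTS.index(mount), TECHNIQUES.index(technique)))
    return int(ss.generate_state(1)[0] % (2**31))


def run_full_protocol(
    study: StudyBundle,
    base_seed: Optional[int] = None,
    min_count_s: int = 11,
    plans=None,
    ethogram: Optional[Ethogram] = None,
    rf_params: Optional[_models.RFParams] = None,
    som_params: Optional[_models.SOMParams] = None,
    mounts: Sequence[str] = MOUNTS,
    techniques: Sequence[str] = TECHNIQUES,
    datasets: Optional[dict[str, pd.DataFrame]] = None,
) -> dict[tuple[str, str], list[RoundResult]]:
    """Fixed-plan modelling rounds for every mount x technique.

    Returns ``{(mount, technique): [RoundResult, ...]}`` — with both
    mounts, both techniques and the four study plans this is 16 trained
    and evaluated models. ``datasets`` can supply pre-extracted labelled
    datasets per mount (saves recomputation); otherwise they are built
    from the study bundle.
    """
    if base_seed is None:
        base_seed = study.config.seed
    if plans is None:
        plans = study_round_plans()
    ethogram = ethogram or default_ethogram()
    results: dict[tuple[str, str], list[RoundResult]] = {}
    for mount in mounts:
        if datasets is not None and mount in datasets:
            data = datasets[mount]
        else:
            data = annotated_dataset(study, mount)
        data, report = preprocess_dataset(data, min_count_s=min_count_s)
        logger.info("%s: %d labelled epochs in %d classes after filtering",
                    mount, len(data), data["label"].nunique())
        for technique in techniques:
            cfg = SelectionConfig(seed=_combo_seed(base_seed, mount, technique))
            results[(mount, technique)] = run_modelling_rounds(
                data, technique, cfg=cfg, plans=plans, ethogram=ethogram,
                rf_params=rf_params, som_params=som_params)
    return results


def protocol_report(results: Mapping[tuple[str, str], list[RoundResult]]
                    ) -> pd.DataFrame:
    """Flat kappa/accuracy table over all runs (round x mount x technique)."""
    from .model_selection import round_report

    frames = [round_report(rs) for rs in results.values()]
    return (pd.concat(frames, ignore_index=True)
            .sort_values(["mount", "technique", "round"])
            .reset_index(drop=True))
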