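"""Decision-stump ligand classification and active-learning reselection.

A ligand is "active" if it ever drove a reaction above the yield threshold
across the products it was screened against. A single-node decision tree
(stump) over the ligand descriptor table then identifies the descriptor and
cut that best separates active from inactive ligands — with the computed
Cu-L interaction distance the expected winner — and that stump is used to
select new candidate ligands predicted active.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import (
    OFF,
    ON,
    BinaryMetrics,
    LigandRecord,
    ValidationError,
    evaluate_binary,
    label_outcome,
)

logger = logging.getLogger(__name__)

ON_IF_BELOW = "on_if_below"
ON_IF_ABOVE = "on_if_above"


@dataclass(frozen=True)
class Stump:
    """A single-feature threshold classifier.

    Boundary convention: a value exactly equal to ``threshold`` falls on the
    *below* side (so ``on_if_below`` maps it to ``on``).
    """

    feature_name: str
    threshold: float
    polarity: str
    train_metrics: BinaryMetrics | None = None

    def predict_value(self, value: float) -> str:
        below = float(value) <= self.threshold
        if self.polarity == ON_IF_BELOW:
            return ON if below else OFF
        return OFF if below else ON

    def margin(self, value: float) -> float:
        """Signed distance to the cut; positive on the ``on`` side."""
        delta = self.threshold - float(value)
        return delta if self.polarity == ON_IF_BELOW else -delta

    def to_json(self) -> str:
        payload = asdict(self)
        if self.train_metrics is not None:
            payload["train_metrics"] = {
                "accuracy": self.train_metrics.accuracy,
                "f1": self.train_metrics.f1,
                "n": self.train_metrics.n,
                "confusion": self.train_metrics.confusion,
            }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "Stump":
        payload = json.loads(text)
        metrics = payload.get("train_metrics")
        tm = None
        if metrics is not None:
            tm = BinaryMetrics(
                accuracy=metrics["accuracy"],
                f1=metrics["f1"],
                n=metrics["n"],
                confusion=tuple(tuple(row) for row in metrics["confusion"]),
            )
        return cls(
            feature_name=payload["feature_name"],
            threshold=float(payload["threshold"]),
            polarity=payload["polarity"],
            train_metrics=tm,
        )


def ligand_activity_labels(
    reactions: pd.DataFrame, threshold: float = 20.0
) -> pd.Series:
    """Per-ligand on/off labels: ``on`` iff the ligand's max yield exceeds *threshold*.

    *reactions* is a long-format table with ``ligand_id`` and ``yield_percent``
    columns. Ligands absent from the table are simply not labeled.
    """
    for col in ("ligand_id", "yield_percent"):
        if col not in reactions.columns:
            raise ValidationError(f"reactions table is missing column {col!r}")
    if reactions.empty:
        raise ValidationError("reactions table is empty; no ligand can be labeled")
    max_yield = reactions.groupby("ligand_id")["yield_percent"].max()
    return pd.Series(
        {lig: label_outcome(y, threshold) for lig, y in max_yield.items()},
        name="activity",
    ).sort_index()


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    distinct = np.unique(values)
    if distinct.size < 2:
        return np.empty(0)
    return (distinct[:-1] + distinct[1:]) / 2.0


def fit_stump(features: pd.DataFrame, labels: Mapping[str, str] | pd.Series) -> Stump:
    """Exhaustive best single-feature threshold classifier.

    Searches every feature column, every midpoint of consecutive distinct
    values, and both polarities; returns the maximum-accuracy stump. Ties are
    broken by larger F1, then larger margin (distance from the cut to the
    nearest training value), then lexicographically smaller feature name,
    smaller threshold, and ``on_if_below`` first.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    ids = [i for i in features.index if i in labels]
    if len(ids) < len(features.index):
        missing = sorted(set(features.index) - set(ids))
        logger.warning("%d ligands lack labels and are excluded: %s", len(missing), missing)
    if len(ids) < 2:
        raise ValidationError("fit_stump requires at least 2 labeled ligands")
    observed = [labels[i] for i in ids]
    if len(set(observed)) < 2:
        raise ValidationError("fit_stump requires both classes in the labels")

    sub = features.loc[ids]
    best: Stump | None = None
    best_key: tuple[float, float, float] | None = None
    for name in sorted(sub.columns):
        col = sub[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValidationError(f"feature {name!r} contains non-finite values")
        for t in _candidate_thresholds(col):
            margin = float(np.min(np.abs(col - t)))
            for polarity in (ON_IF_BELOW, ON_IF_ABOVE):
                stump = Stump(name, float(t), polarity)
                pred = [stump.predict_value(v) for v in col]
                m = evaluate_binary(pred, observed)
                key = (m.accuracy, m.f1, margin)
                if best_key is None or key > best_key:
                    best_key = key
                    best = Stump(name, float(t), polarity, train_metrics=m)
    assert best is not None  # guaranteed: >=2 distinct labels implies >=2 rows
    if best.train_metrics is None or best_key is None:
        raise ValidationError("no candidate threshold found (all features constant?)")
    logger.info(
        "fit_stump: %s @ %.4g (%s), accuracy %.3f / F1 %.3f",
        best.feature_name, best.threshold, best.polarity,
        best.train_metrics.accuracy, best.train_metrics.f1,
    )
    return best


def predict_stump(stump: Stump, features: pd.DataFrame | Mapping[str, float]) -> pd.Series | str:
    """Apply a stump to a feature table (returns a Series) or one mapping (a label)."""
    if isinstance(features, Mapping):
        if stump.feature_name not in features:
            raise ValidationError(f"feature {stump.feature_name!r} missing from input")
        return stump.predict_value(features[stump.feature_name])
    if stump.feature_name not in features.columns:
        raise ValidationError(f"feature {stump.feature_name!r} missing from input table")
    values = features[stump.feature_name]
    return pd.Series(
        [stump.predict_value(v) for v in values], index=features.index, name="predicted"
    )


def select_candidates(
    candidates: Sequence[LigandRecord], stump: Stump
) -> list[LigandRecord]:
    """Candidates predicted ``on``, most confidently-on (largest margin) first."""
    scored: list[tuple[float, str, LigandRecord]] = []
    for lig in candidates:
        value = lig.descriptor(stump.feature_name)
        if stump.predict_value(value) == ON:
            scored.append((stump.margin(value), lig.ligand_id, lig))
    scored.sort(key=lambda item: (-item[0], item[1]))
    return [lig for _, _, lig in scored]
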