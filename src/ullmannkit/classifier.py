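"""Three-node reaction-success decision tree: learned and fixed-rule modes.

The learned mode grows a binary classification tree by best-first greedy
partitioning (Gini impurity, midpoint split candidates) under an
*internal-node budget* — "three nodes" caps the number of feature tests, not
the depth. The fixed-rule mode applies the published thresholds directly:

    on  iff  d <= 2.07 A  and  N-charge <= -0.803 au  and  %VBur <= 33.5

Equality at a threshold is ON for all three tests (every published off
condition is a strict ">"), which differs from the left-closed convention of
some tree libraries and is therefore applied consistently here: a tree node
sends ``value <= threshold`` down the left branch.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split

from .core_model import (
    OFF,
    ON,
    BinaryMetrics,
    ValidationError,
    evaluate_binary,
)

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class FixedRule:
    """Published decision thresholds for the three reaction components."""

    d_max: float = 2.07
    n_charge_max: float = -0.803
    vbur_max: float = 33.5

    def __post_init__(self) -> None:
        if not (self.d_max > 0 and math.isfinite(self.d_max)):
            raise ValidationError(f"d_max must be a positive finite length, got {self.d_max}")
        if not (0 < self.vbur_max < 100):
            raise ValidationError(f"vbur_max must lie in (0, 100), got {self.vbur_max}")
        if not math.isfinite(self.n_charge_max):
            raise ValidationError(f"n_charge_max must be finite, got {self.n_charge_max}")


def predict_fixed(
    d: float, n_charge: float, vbur: float, rule: FixedRule | None = None
) -> str:
    """Fixed-rule prediction; equality at any threshold stays ``on``."""
    rule = rule or FixedRule()
    for name, value in (("d", d), ("n_charge", n_charge), ("vbur", vbur)):
        if value is None or not math.isfinite(float(value)):
            raise ValidationError(f"feature {name!r} is missing or non-finite: {value!r}")
    favorable = (
        float(d) <= rule.d_max
        and float(n_charge) <= rule.n_charge_max
        and float(vbur) <= rule.vbur_max
    )
    return ON if favorable else OFF


def predict_substrate(n_charge: float, vbur: float, rule: FixedRule | None = None) -> str:
    """Substrate-only prediction (ligand axis marginalized to a favorable-d panel)."""
    rule = rule or FixedRule()
    return predict_fixed(rule.d_max, n_charge, vbur, rule)


# ---------------------------------------------------------------------------
# Greedy budgeted tree
# ---------------------------------------------------------------------------


def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = float(np.mean(y))
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray) -> tuple[float, int, float] | None:
    """Best (impurity decrease, feature index, threshold) for one subset.

    Split candidates are midpoints of consecutive distinct values; splits
    leaving an empty side are discarded. Ties keep the earliest feature
    (column order) and the smallest threshold.
    """
    base = _gini(y)
    n = y.size
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        col = X[:, j]
        distinct = np.unique(col)
        if distinct.size < 2:
            continue
        mids = (distinct[:-1] + distinct[1:]) / 2.0
        for t in mids:
            mask = col <= t
            nl = int(mask.sum())
            if nl == 0 or nl == n:
                continue
            dec = base - (nl * _gini(y[mask]) + (n - nl) * _gini(y[~mask])) / n
            if best is None or dec > best[0] + _EPS:
                best = (dec, j, float(t))
    return best


class _Leaf:
    __slots__ = ("idx", "order", "node")

    def __init__(self, idx: np.ndarray, order: int, node: dict):
        self.idx = idx
        self.order = order
        self.node = node


def _leaf_node(y: np.ndarray) -> dict:
    n_on = int(y.sum())
    n = int(y.size)
    # majority label; exact tie resolves to "off" (the conservative call)
    label = ON if n_on * 2 > n else OFF
    return {"label": label, "n": n, "n_on": n_on}


def _grow(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str], max_nodes: int) -> tuple[dict, list[dict]]:
    n_total = y.size
    root = _leaf_node(y)
    frontier = [_Leaf(np.arange(n_total), 0, root)]
    nodes: list[dict] = []
    counter = 1
    while len(nodes) < max_nodes:
        best_leaf: _Leaf | None = None
        best_split: tuple[float, int, float] | None = None
        best_weighted = _EPS
        for leaf in frontier:
            split = _best_split(X[leaf.idx], y[leaf.idx])
            if split is None:
                continue
            weighted = split[0] * leaf.idx.size / n_total
            if weighted > best_weighted + _EPS or (
                best_leaf is not None
                and abs(weighted - best_weighted) <= _EPS
                and leaf.order < best_leaf.order
            ):
                best_leaf, best_split, best_weighted = leaf, split, weighted
        if best_leaf is None or best_split is None:
            break
        _, j, t = best_split
        idx = best_leaf.idx
        mask = X[idx, j] <= t
        left_idx, right_idx = idx[mask], idx[~mask]
        left = _leaf_node(y[left_idx])
        right = _leaf_node(y[right_idx])
        node = best_leaf.node
        node.clear()
        on_frac_left = left["n_on"] / max(left["n"], 1)
        on_frac_right = right["n_on"] / max(right["n"], 1)
        node.update(
            feature=feature_names[j],
            threshold=t,
            left=left,
            right=right,
            off_branch="above" if on_frac_right <= on_frac_left else "below",
        )
        nodes.append(
            {"feature": feature_names[j], "threshold": t, "off_branch": node["off_branch"]}
        )
        frontier.remove(best_leaf)
        frontier.append(_Leaf(left_idx, counter, left))
        frontier.append(_Leaf(right_idx, counter + 1, right))
        counter += 2
    return root, nodes


def _predict_node(node: dict, row: Mapping[str, float]) -> str:
    while "label" not in node:
        name = node["feature"]
        if name not in row or row[name] is None:
            raise ValidationError(f"feature {name!r} missing from prediction input")
        node = node["left"] if float(row[name]) <= node["threshold"] else node["right"]
    return node["label"]


@dataclass
class TreeModel:
    """A fitted budgeted decision tree plus its bookkeeping."""

    root: dict
    nodes: list[dict]
    feature_names: list[str]
    max_nodes: int
    seed: int | None = None
    train_metrics: BinaryMetrics | None = None
    test_metrics: BinaryMetrics | None = None
    cv_mean_accuracy: float | None = None

    def predict_row(self, row: Mapping[str, float]) -> str:
        return _predict_node(self.root, row)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise ValidationError(f"prediction input is missing feature columns {missing}")
        return pd.Series(
            [self.predict_row(row) for row in features.to_dict("records")],
            index=features.index,
            name="predicted",
        )

    def to_json(self) -> str:
        def metrics(m: BinaryMetrics | None):
            if m is None:
                return None
            return {"accuracy": m.accuracy, "f1": m.f1, "n": m.n, "confusion": m.confusion}

        return json.dumps(
            {
                "root": self.root,
                "nodes": self.nodes,
                "feature_names": self.feature_names,
                "max_nodes": self.max_nodes,
                "seed": self.seed,
                "train_metrics": metrics(self.train_metrics),
                "test_metrics": metrics(self.test_metrics),
                "cv_mean_accuracy": self.cv_mean_accuracy,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        payload = json.loads(text)

        def metrics(m):
            if m is None:
                return None
            return BinaryMetrics(
                accuracy=m["accuracy"],
                f1=m["f1"],
                n=m["n"],
                confusion=tuple(tuple(r) for r in m["confusion"]),
            )

        return cls(
            root=payload["root"],
            nodes=payload["nodes"],
            feature_names=list(payload["feature_names"]),
            max_nodes=int(payload["max_nodes"]),
            seed=payload.get("seed"),
            train_metrics=metrics(payload.get("train_metrics")),
            test_metrics=metrics(payload.get("test_metrics")),
            cv_mean_accuracy=payload.get("cv_mean_accuracy"),
        )


def _validate_training_input(
    features: pd.DataFrame, labels: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    if len(features) != len(labels):
        raise ValidationError(
            f"features ({len(features)}) and labels ({len(labels)}) lengths differ"
        )
    y = np.asarray([lab == ON for lab in labels])
    if y.all() or not y.any():
        raise ValidationError("training labels contain a single class")
    X = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature table contains non-finite values")
    return X, y, list(features.columns)


def fit_tree(features: pd.DataFrame, labels: Sequence[str], max_nodes: int = 3) -> TreeModel:
    """Fit the budgeted tree on all rows (no held-out split)."""
    X, y, names = _validate_training_input(features, labels)
    root, nodes = _grow(X, y, names, max_nodes)
    model = TreeModel(root=root, nodes=nodes, feature_names=names, max_nodes=max_nodes)
    model.train_metrics = evaluate_binary(list(model.predict(features)), list(labels))
    return model


def train_tree(
    features: pd.DataFrame,
    labels: Sequence[str],
    max_nodes: int = 3,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> TreeModel:
    """Train/test-split fit with held-out metrics (stratified random split)."""
    if len(features) < 20:
        raise ValidationError(f"train_tree requires n >= 20, got {len(features)}")
    _validate_training_input(features, labels)
    labels = list(labels)
    idx = np.arange(len(features))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=labels
    )
    train_labels = [labels[i] for i in train_idx]
    test_labels = [labels[i] for i in test_idx]
    model = fit_tree(features.iloc[train_idx], train_labels, max_nodes=max_nodes)
    model.seed = seed
    model.test_metrics = evaluate_binary(
        list(model.predict(features.iloc[test_idx])), test_labels
    )
    logger.info(
        "train_tree: %d nodes, train accuracy %.3f, test accuracy %.3f",
        len(model.nodes),
        model.train_metrics.accuracy if model.train_metrics else float("nan"),
        model.test_metrics.accuracy,
    )
    return model


@dataclass(frozen=True)
class CVResult:
    fold_accuracies: tuple[float, ...]
    mean_accuracy: float

    def __float__(self) -> float:
        return self.mean_accuracy


def cross_validate(
    features: pd.DataFrame,
    labels: Sequence[str],
    folds: int = 4,
    seed: int = 0,
    max_nodes: int = 3,
) -> CVResult:
    """Stratified k-fold accuracy of the budgeted tree (falls back to plain
    k-fold when a class is rarer than the fold count)."""
    if folds < 2:
        raise ValidationError(f"folds must be >= 2, got {folds}")
    if len(features) < folds:
        raise ValidationError(f"n = {len(features)} is smaller than folds = {folds}")
    _validate_training_input(features, labels)
    labels = list(labels)
    counts = pd.Series(labels).value_counts()
    if counts.min() >= folds:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=folds, shuffle=True, random_state=seed)
    accs: list[float] = []
    for train_idx, test_idx in splitter.split(features, labels):
        fold_train = [labels[i] for i in train_idx]
        if len(set(fold_train)) < 2:
            raise ValidationError(
                "a CV training fold contains a single class; reduce folds"
            )
        model = fit_tree(features.iloc[train_idx], fold_train, max_nodes=max_nodes)
        pred = model.predict(features.iloc[test_idx])
        fold_test = [labels[i] for i in test_idx]
        accs.append(evaluate_binary(list(pred), fold_test).accuracy)
    return CVResult(fold_accuracies=tuple(accs), mean_accuracy=float(np.mean(accs)))


def assemble_features(
    reactions: pd.DataFrame,
    products: pd.DataFrame,
    ligands: pd.DataFrame,
    bromides: pd.DataFrame,
    amines: pd.DataFrame,
) -> pd.DataFrame:
    """Join the long-format tables into a per-reaction (d, n_charge, vbur, yield) table."""
    merged = reactions.merge(products, on="product_id", how="left", validate="m:1")
    merged = merged.merge(
        ligands[["ligand_id", "cu_l_distance"]], on="ligand_id", how="left", validate="m:1"
    )
    merged = merged.merge(bromides[["bromide_id", "vbur"]], on="bromide_id", how="left")
    merged = merged.merge(amines[["amine_id", "n_charge"]], on="amine_id", how="left")
    merged = merged.rename(columns={"cu_l_distance": "d"})
    for col in ("d", "n_charge", "vbur"):
        if merged[col].isna().any():
            bad = merged.loc[merged[col].isna(), ["product_id", "ligand_id"]]
            raise ValidationError(
                f"unresolvable {col!r} for reactions: {bad.to_records(index=False).tolist()[:5]}"
            )
    return merged[["product_id", "ligand_id", "d", "n_charge", "vbur", "yield_percent"]]
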