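"""Core domain types, on/off outcome labeling, control curation, and binary metrics.

Everything downstream (screening, classification, confidence maps, the
recommender) builds on the record types and the two conventions fixed here:

* a reaction is ``on`` iff its assay yield *strictly exceeds* the yield
  threshold (default 20%, i.e. two catalytic turnovers at 10 mol% loading);
* a product fails curation iff *either* of its two control experiments
  (ligand-free, and ligand- and copper-free) reaches the control threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

ON = "on"
OFF = "off"

#: Yields above 100% are tolerated up to this bound (assay calibration noise).
MAX_YIELD = 150.0

DEFAULT_YIELD_THRESHOLD = 20.0
DEFAULT_CONTROL_THRESHOLD = 20.0


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition or schema."""


class LigandClass(str, Enum):
    neutral = "neutral"
    diketone = "diketone"
    oxalamide = "oxalamide"
    anilino_oxo_acetic_acid = "anilino_oxo_acetic_acid"
    other = "other"


class ChargeState(str, Enum):
    neutral = "neutral"
    anionic = "anionic"


class ControlType(str, Enum):
    no_ligand = "no_ligand"
    no_ligand_no_cu = "no_ligand_no_cu"


def _require_finite(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


def check_yield(yield_percent: float, context: str = "yield_percent") -> float:
    """Validate an assay yield: finite, >= 0, <= MAX_YIELD (warn above 100%)."""
    y = float(yield_percent)
    if not math.isfinite(y) or y < 0:
        raise ValidationError(f"{context} must be a finite value >= 0, got {yield_percent!r}")
    if y > MAX_YIELD:
        raise ValidationError(f"{context} = {y} exceeds the sanity bound of {MAX_YIELD}%")
    if y > 100:
        logger.warning("%s = %.1f%% exceeds 100%% (accepted as assay noise)", context, y)
    return y


@dataclass(frozen=True)
class LigandRecord:
    """A ligand with its computed Cu-ligand interaction distance (Angstrom)."""

    ligand_id: str
    cu_l_distance: float
    ligand_class: str = LigandClass.other.value
    charge_state: str = ChargeState.neutral.value
    extra_descriptors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        d = _require_finite(self.cu_l_distance, "cu_l_distance")
        if d <= 0:
            raise ValidationError(f"cu_l_distance must be > 0, got {d} for {self.ligand_id}")
        LigandClass(self.ligand_class)
        ChargeState(self.charge_state)

    def descriptor(self, name: str) -> float:
        if name == "cu_l_distance":
            return self.cu_l_distance
        if self.extra_descriptors and name in self.extra_descriptors:
            return float(self.extra_descriptors[name])
        raise ValidationError(f"ligand {self.ligand_id} has no descriptor {name!r}")


@dataclass(frozen=True)
class BromideRecord:
    """An aryl bromide with its percent buried volume at 2.5 A radius."""

    bromide_id: str
    vbur: float
    extra_descriptors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        v = _require_finite(self.vbur, "vbur")
        if not (0 < v < 100):
            raise ValidationError(f"vbur must lie in (0, 100), got {v} for {self.bromide_id}")


@dataclass(frozen=True)
class AmineRecord:
    """A primary amine with its nitrogen NBO partial charge (atomic units)."""

    amine_id: str
    n_charge: float
    extra_descriptors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        _require_finite(self.n_charge, "n_charge")


@dataclass(frozen=True)
class ProductRecord:
    """A coupling product: one (aryl bromide, primary amine) pair."""

    product_id: str
    bromide_id: str
    amine_id: str


@dataclass(frozen=True)
class ReactionResult:
    product_id: str
    ligand_id: str
    yield_percent: float

    def __post_init__(self) -> None:
        check_yield(self.yield_percent, f"yield for ({self.product_id}, {self.ligand_id})")


@dataclass(frozen=True)
class ControlResult:
    product_id: str
    control_type: str
    yield_percent: float

    def __post_init__(self) -> None:
        ControlType(self.control_type)
        check_yield(self.yield_percent, f"control yield for {self.product_id}")


@dataclass(frozen=True)
class BinaryMetrics:
    """Accuracy / F1 with ``on`` as the positive class.

    ``confusion`` follows the (observed row, predicted column) layout with
    class order [off, on]: ``[[TN, FP], [FN, TP]]``.
    """

    accuracy: float
    f1: float
    n: int
    confusion: tuple[tuple[int, int], tuple[int, int]]

    @property
    def tn(self) -> int:
        return self.confusion[0][0]

    @property
    def fp(self) -> int:
        return self.confusion[0][1]

    @property
    def fn(self) -> int:
        return self.confusion[1][0]

    @property
    def tp(self) -> int:
        return self.confusion[1][1]


def label_outcome(yield_percent: float, threshold: float = DEFAULT_YIELD_THRESHOLD) -> str:
    """Classify a yield as ``on``/``off``; ``on`` iff it strictly exceeds *threshold*."""
    y = check_yield(yield_percent)
    return ON if y > threshold else OFF


def apply_control_filter(
    products: Sequence[ProductRecord],
    controls: Iterable[ControlResult],
    control_threshold: float = DEFAULT_CONTROL_THRESHOLD,
) -> tuple[list[ProductRecord], list[ProductRecord]]:
    """Partition products into (passing, failed) by their control experiments.

    A product fails iff either its ``no_ligand`` or ``no_ligand_no_cu``
    control reaches *control_threshold* — evidence of a non-catalytic
    background pathway (e.g. SNAr). Every product must have exactly both
    control rows; violations raise :class:`ValidationError`.
    """
    by_product: dict[str, dict[str, float]] = {}
    for c in controls:
        by_product.setdefault(c.product_id, {})[c.control_type] = c.yield_percent

    passing: list[ProductRecord] = []
    failed: list[ProductRecord] = []
    for p in products:
        rows = by_product.get(p.product_id, {})
        for ct in (ControlType.no_ligand.value, ControlType.no_ligand_no_cu.value):
            if ct not in rows:
                raise ValidationError(
                    f"product {p.product_id} is missing its {ct!r} control row"
                )
        reasons = [
            f"{ct}={rows[ct]:.1f}%" for ct in rows if rows[ct] >= control_threshold
        ]
        if reasons:
            logger.info(
                "product %s failed control filtering (%s >= %.1f%%)",
                p.product_id, ", ".join(reasons), control_threshold,
            )
            failed.append(p)
        else:
            passing.append(p)
    return passing, failed


def evaluate_binary(predicted: Sequence[str], observed: Sequence[str]) -> BinaryMetrics:
    """Accuracy, F1 (positive class ``on``) and the 2x2 confusion table."""
    if len(predicted) != len(observed):
        raise ValidationError(
            f"predicted ({len(predicted)}) and observed ({len(observed)}) lengths differ"
        )
    if len(predicted) == 0:
        raise ValidationError("cannot evaluate empty label lists")
    for lab in (*predicted, *observed):
        if lab not in (ON, OFF):
            raise ValidationError(f"unknown label {lab!r}; expected 'on' or 'off'")

    pred = np.asarray([p == ON for p in predicted])
    obs = np.asarray([o == ON for o in observed])
    tp = int(np.sum(pred & obs))
    tn = int(np.sum(~pred & ~obs))
    fp = int(np.sum(pred & ~obs))
    fn = int(np.sum(~pred & obs))
    n = len(predicted)
    accuracy = (tp + tn) / n
    denom = 2 * tp + fp + fn
    f1 = (2 * tp / denom) if denom else 0.0
    return BinaryMetrics(accuracy=accuracy, f1=f1, n=n, confusion=((tn, fp), (fn, tp)))
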