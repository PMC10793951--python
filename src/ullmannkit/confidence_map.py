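"""Entropy-based prediction confidence and its RBF-interpolated map.

Per product, the fraction of screened ligands that came out ``on`` defines a
binary outcome distribution whose information entropy (base 10 by default —
the base that reproduces the worked 2-of-18 -> 15% uncertainty example) is
the prediction uncertainty; confidence is its complement. Confidences are
signed by the predicted class (+ for on, - for off) and interpolated over
the two substrate node-features (amine N charge, bromide %VBur) with a
radial-basis-function interpolant, giving a queryable confidence surface.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import RBFInterpolator

from .core_model import OFF, ON, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_ENTROPY_BASE = 10.0
DEFAULT_MIN_LIGANDS = 6

#: map from public kernel names to scipy RBFInterpolator kernels
_KERNELS = {
    "thin_plate": "thin_plate_spline",
    "multiquadric": "multiquadric",
    "gaussian": "gaussian",
}


def entropy10(p: float, base: float = DEFAULT_ENTROPY_BASE) -> float:
    """Binary information entropy of (p, 1-p) in the given log base.

    ``0 * log(0)`` is taken as 0, so the endpoints return exactly 0.
    """
    p = float(p)
    if not (0.0 <= p <= 1.0) or not math.isfinite(p):
        raise ValidationError(f"p must lie in [0, 1], got {p!r}")
    if base <= 0 or base == 1:
        raise ValidationError(f"entropy base must be positive and != 1, got {base}")
    total = 0.0
    for q in (p, 1.0 - p):
        if q > 0.0:
            total -= q * math.log(q, base)
    return total


@dataclass(frozen=True)
class ConfidencePoint:
    product_id: str
    coords: tuple[float, float]  # (n_charge in au, vbur in %)
    predicted: str
    n_ligands: int
    n_on: int
    uncertainty: float
    confidence: float
    signed_score: float


def product_confidence(
    outcomes: Sequence[str],
    predicted: str,
    coords: tuple[float, float],
    product_id: str = "",
    min_ligands: int = DEFAULT_MIN_LIGANDS,
    base: float = DEFAULT_ENTROPY_BASE,
) -> ConfidencePoint:
    """Confidence for one product from its per-ligand on/off outcomes."""
    n = len(outcomes)
    if n < min_ligands:
        raise ValidationError(
            f"product {product_id or '<unnamed>'} has {n} ligand outcomes; "
            f"at least {min_ligands} required (min_ligands)"
        )
    if predicted not in (ON, OFF):
        raise ValidationError(f"predicted must be 'on' or 'off', got {predicted!r}")
    for lab in outcomes:
        if lab not in (ON, OFF):
            raise ValidationError(f"unknown outcome label {lab!r}")
    n_on = sum(1 for lab in outcomes if lab == ON)
    uncertainty = entropy10(n_on / n, base=base)
    confidence = 1.0 - uncertainty
    signed = confidence if predicted == ON else -confidence
    return ConfidencePoint(
        product_id=product_id,
        coords=(float(coords[0]), float(coords[1])),
        predicted=predicted,
        n_ligands=n,
        n_on=n_on,
        uncertainty=uncertainty,
        confidence=confidence,
        signed_score=signed,
    )


@dataclass
class ConfidenceMap:
    points: list[ConfidencePoint]
    kernel: str
    smoothing: float
    axis_mean: tuple[float, float]
    axis_std: tuple[float, float]
    _interp: RBFInterpolator | None = field(default=None, repr=False, compare=False)

    def standardize(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, dtype=float) - np.asarray(self.axis_mean)) / np.asarray(
            self.axis_std
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": self.kernel,
                "smoothing": self.smoothing,
                "axis_mean": list(self.axis_mean),
                "axis_std": list(self.axis_std),
                "points": [
                    {
                        "product_id": p.product_id,
                        "coords": list(p.coords),
                        "predicted": p.predicted,
                        "n_ligands": p.n_ligands,
                        "n_on": p.n_on,
                        "uncertainty": p.uncertainty,
                        "confidence": p.confidence,
                        "signed_score": p.signed_score,
                    }
                    for p in self.points
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ConfidenceMap":
        payload = json.loads(text)
        points = [
            ConfidencePoint(
                product_id=p["product_id"],
                coords=tuple(p["coords"]),
                predicted=p["predicted"],
                n_ligands=p["n_ligands"],
                n_on=p["n_on"],
                uncertainty=p["uncertainty"],
                confidence=p["confidence"],
                signed_score=p["signed_score"],
            )
            for p in payload["points"]
        ]
        return fit_map(points, kernel=payload["kernel"], smoothing=payload["smoothing"])


def _build_interpolant(
    coords: np.ndarray, values: np.ndarray, kernel: str, smoothing: float
) -> RBFInterpolator:
    kwargs: dict = {"kernel": _KERNELS[kernel], "smoothing": smoothing}
    if kernel in ("multiquadric", "gaussian"):
        kwargs["epsilon"] = 1.0
    return RBFInterpolator(coords, values, **kwargs)


def fit_map(
    points: Sequence[ConfidencePoint],
    kernel: str = "thin_plate",
    smoothing: float = 0.0,
) -> ConfidenceMap:
    """Fit the signed-score interpolant over standardized substrate coordinates.

    Duplicate coordinates are merged by averaging their signed scores (with a
    warning); a singular system (e.g. all points collinear) falls back to the
    multiquadric kernel.
    """
    if kernel not in _KERNELS:
        raise ValidationError(f"unknown kernel {kernel!r}; choose from {sorted(_KERNELS)}")
    if smoothing < 0:
        raise ValidationError(f"smoothing must be >= 0, got {smoothing}")
    points = list(points)
    if len(points) < 3:
        raise ValidationError(f"fit_map requires >= 3 points, got {len(points)}")

    raw = np.asarray([p.coords for p in points], dtype=float)
    mean = raw.mean(axis=0)
    std = raw.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    coords = (raw - mean) / std
    values = np.asarray([p.signed_score for p in points], dtype=float)

    # merge duplicates in standardized space
    keys = np.round(coords, 9)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    if inverse.max() + 1 < len(points):
        logger.warning(
            "fit_map: %d duplicate coordinate groups averaged",
            len(points) - (inverse.max() + 1),
        )
        merged_coords = np.vstack(
            [coords[inverse == g].mean(axis=0) for g in range(inverse.max() + 1)]
        )
        merged_values = np.asarray(
            [values[inverse == g].mean() for g in range(inverse.max() + 1)]
        )
        coords, values = merged_coords, merged_values
        if len(values) < 3:
            raise ValidationError("fewer than 3 distinct coordinates after merging")

    try:
        interp = _build_interpolant(coords, values, kernel, smoothing)
    except np.linalg.LinAlgError:
        logger.warning("fit_map: singular %s system; falling back to multiquadric", kernel)
        kernel = "multiquadric"
        interp = _build_interpolant(coords, values, kernel, smoothing)

    return ConfidenceMap(
        points=points,
        kernel=kernel,
        smoothing=float(smoothing),
        axis_mean=(float(mean[0]), float(mean[1])),
        axis_std=(float(std[0]), float(std[1])),
        _interp=interp,
    )


@dataclass(frozen=True)
class MapQuery:
    signed_score: float
    predicted: str | None
    confidence: float
    extrapolated: bool
    ambiguous: bool


def query_map(cmap: ConfidenceMap, coords: tuple[float, float]) -> MapQuery:
    """Evaluate the confidence surface at (n_charge, vbur).

    The score magnitude is clipped to [0, 1]; the class is its sign. Queries
    more than 3 standardized units from the data centroid on either axis are
    flagged ``extrapolated``; a score within 1e-9 of zero is ``ambiguous``
    (no class call).
    """
    if cmap._interp is None:
        raise ValidationError("map has no fitted interpolant")
    z = cmap.standardize(np.asarray(coords, dtype=float).reshape(1, 2))
    raw = float(cmap._interp(z)[0])
    extrapolated = bool(np.any(np.abs(z) > 3.0))
    ambiguous = abs(raw) < 1e-9
    predicted: str | None
    if ambiguous:
        predicted = None
    else:
        predicted = ON if raw > 0 else OFF
    confidence = min(abs(raw), 1.0)
    return MapQuery(
        signed_score=raw,
        predicted=predicted,
        confidence=confidence,
        extrapolated=extrapolated,
        ambiguous=ambiguous,
    )
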