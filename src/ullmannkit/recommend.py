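"""Empirical nearest-neighbor ligand recommendation.

For a query product, find its two nearest neighbors in the standardized
(amine N charge, bromide %VBur) substrate space and pool each neighbor's
top-three ligands by yield; ligands supported by both neighbors are flagged.
The leave-self-out hit rate measures how often a product's own top ligands
appear in the recommendation built from its neighbors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core_model import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_K = 2
DEFAULT_TOP_N = 3


@dataclass(frozen=True)
class Recommendation:
    query_id: str
    neighbor_ids: tuple[str, ...]
    neighbor_distances: tuple[float, ...]
    ligand_ids: tuple[str, ...]
    shared: frozenset[str]
    provenance: dict[str, tuple[tuple[str, float], ...]]  # ligand -> ((neighbor, yield), ...)


def top_ligands(reactions: pd.DataFrame, top_n: int = DEFAULT_TOP_N) -> list[str]:
    """Top-``top_n`` ligands of one product by yield (ties lexicographic).

    *reactions* holds the rows for a single product. Fewer than ``top_n``
    tested ligands returns them all with a warning.
    """
    for col in ("ligand_id", "yield_percent"):
        if col not in reactions.columns:
            raise ValidationError(f"reactions table is missing column {col!r}")
    if reactions.empty:
        raise ValidationError("no reactions given; cannot rank ligands")
    ranked = sorted(
        reactions[["ligand_id", "yield_percent"]].itertuples(index=False),
        key=lambda r: (-r.yield_percent, r.ligand_id),
    )
    if len(ranked) < top_n:
        logger.warning(
            "only %d tested ligands available (top_n=%d); returning all", len(ranked), top_n
        )
    return [r.ligand_id for r in ranked[:top_n]]


def _standardizer(coords: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = coords[["n_charge", "vbur"]].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


def nearest_products(
    query_coords: tuple[float, float],
    coords: pd.DataFrame,
    k: int = DEFAULT_K,
    exclude: str | None = None,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[tuple[str, float]]:
    """The ``k`` nearest dataset products to the query in standardized space.

    *coords* must have columns ``product_id``, ``n_charge``, ``vbur``. The
    query itself can be excluded by id. Distance ties break lexicographically.
    """
    for col in ("product_id", "n_charge", "vbur"):
        if col not in coords.columns:
            raise ValidationError(f"coords table is missing column {col!r}")
    pool = coords if exclude is None else coords[coords["product_id"] != exclude]
    if len(pool) < k:
        raise ValidationError(f"only {len(pool)} candidate products for k={k}")
    mean, std = scaler if scaler is not None else _standardizer(coords)
    X = (pool[["n_charge", "vbur"]].to_numpy(dtype=float) - mean) / std
    q = (np.asarray(query_coords, dtype=float).reshape(1, 2) - mean) / std
    dists = cdist(q, X)[0]
    order = sorted(zip(dists, pool["product_id"].tolist()), key=lambda t: (t[0], t[1]))
    return [(pid, float(d)) for d, pid in order[:k]]


def recommend_ligands(
    query_coords: tuple[float, float],
    reactions: pd.DataFrame,
    coords: pd.DataFrame,
    query_id: str = "",
    k: int = DEFAULT_K,
    top_n: int = DEFAULT_TOP_N,
) -> Recommendation:
    """Pooled top-ligand recommendation from the query's nearest neighbors.

    The ligand list is the deduplicated union — neighbor-1's top list first,
    then neighbor-2 novelties — and ligands present in every neighbor's top
    list are flagged ``shared``.
    """
    neighbors = nearest_products(query_coords, coords, k=k, exclude=query_id or None)
    per_neighbor: dict[str, list[str]] = {}
    yields: dict[tuple[str, str], float] = {}
    for pid, _dist in neighbors:
        rows = reactions[reactions["product_id"] == pid]
        tops = top_ligands(rows, top_n=top_n)
        per_neighbor[pid] = tops
        for lig in tops:
            yields[(pid, lig)] = float(
                rows.loc[rows["ligand_id"] == lig, "yield_percent"].iloc[0]
            )

    ordered: list[str] = []
    for pid, _dist in neighbors:
        for lig in per_neighbor[pid]:
            if lig not in ordered:
                ordered.append(lig)
    shared = frozenset(
        lig for lig in ordered if all(lig in tops for tops in per_neighbor.values())
    )
    provenance = {
        lig: tuple(
            (pid, yields[(pid, lig)]) for pid, _ in neighbors if lig in per_neighbor[pid]
        )
        for lig in ordered
    }
    return Recommendation(
        query_id=query_id,
        neighbor_ids=tuple(pid for pid, _ in neighbors),
        neighbor_distances=tuple(d for _, d in neighbors),
        ligand_ids=tuple(ordered),
        shared=shared,
        provenance=provenance,
    )


def neighbor_hit_rate(
    reactions: pd.DataFrame,
    coords: pd.DataFrame,
    k: int = DEFAULT_K,
    top_n: int = DEFAULT_TOP_N,
) -> float:
    """Leave-self-out fraction of products whose own top ligands overlap the
    recommendation assembled from their nearest neighbors."""
    product_ids = coords["product_id"].tolist()
    if len(product_ids) < k + 1:
        raise ValidationError(f"need at least {k + 1} products for k={k}")
    hits = 0
    for _, row in coords.iterrows():
        pid = row["product_id"]
        own = set(top_ligands(reactions[reactions["product_id"] == pid], top_n=top_n))
        rec = recommend_ligands(
            (row["n_charge"], row["vbur"]),
            reactions,
            coords,
            query_id=pid,
            k=k,
            top_n=top_n,
        )
        if own & set(rec.ligand_ids):
            hits += 1
    return hits / len(product_ids)
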