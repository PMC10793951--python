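"""Training-set curation stage: library filtering, chemical-space embedding,
Ward clustering, representative picking, and cross-cluster product pairing."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering

from .core_model import ProductRecord, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_LOGP_MAX = 4.0
DEFAULT_MW_MAX = 400.0
DEFAULT_N_NEIGHBORS = 15
DEFAULT_MIN_DIST = 0.1
DEFAULT_SEED = 42


@dataclass(frozen=True)
class CandidateRecord:
    candidate_id: str
    logp: float
    mol_weight: float
    cost_rank: float
    descriptors: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name in ("logp", "mol_weight", "cost_rank"):
            value = getattr(self, name)
            if value is None or not math.isfinite(float(value)):
                raise ValidationError(
                    f"candidate {self.candidate_id}: {name} missing or non-finite ({value!r})"
                )
        if self.cost_rank < 0:
            raise ValidationError(
                f"candidate {self.candidate_id}: cost_rank must be >= 0"
            )
        if self.descriptors:
            bad = [k for k, v in self.descriptors.items() if not math.isfinite(float(v))]
            if bad:
                raise ValidationError(
                    f"candidate {self.candidate_id}: non-finite descriptors {bad}"
                )


@dataclass(frozen=True)
class SpaceEmbedding:
    candidate_ids: tuple[str, ...]
    coords: np.ndarray  # n x 2
    params: dict
    seed: int


@dataclass(frozen=True)
class Clustering:
    candidate_ids: tuple[str, ...]
    labels: tuple[int, ...]
    k: int

    def members(self, label: int) -> list[str]:
        return [c for c, l in zip(self.candidate_ids, self.labels) if l == label]


def filter_library(
    candidates: Sequence[CandidateRecord],
    logp_max: float = DEFAULT_LOGP_MAX,
    mw_max: float = DEFAULT_MW_MAX,
) -> list[CandidateRecord]:
    """Retain candidates with logp < logp_max AND mol_weight < mw_max (strict)."""
    kept = [c for c in candidates if c.logp < logp_max and c.mol_weight < mw_max]
    logger.info("filter_library: kept %d of %d candidates", len(kept), len(candidates))
    return kept


def _standardize(X: np.ndarray, context: str) -> np.ndarray:
    if not np.all(np.isfinite(X)):
        raise ValidationError(f"{context}: matrix contains non-finite values")
    std = X.std(axis=0, ddof=0)
    constant = std == 0
    if constant.any():
        logger.warning(
            "%s: dropping %d constant column(s)", context, int(constant.sum())
        )
        X = X[:, ~constant]
        std = std[~constant]
    if X.shape[1] < 1:
        raise ValidationError(f"{context}: no varying columns remain")
    return (X - X.mean(axis=0)) / std


def embed_space(
    descriptor_matrix: np.ndarray | pd.DataFrame,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    min_dist: float = DEFAULT_MIN_DIST,
    seed: int = DEFAULT_SEED,
    candidate_ids: Sequence[str] | None = None,
) -> SpaceEmbedding:
    """2-D UMAP embedding of a standardized descriptor matrix (deterministic per seed)."""
    import umap  # deferred: numba-backed import is slow

    if isinstance(descriptor_matrix, pd.DataFrame):
        if candidate_ids is None:
            candidate_ids = [str(i) for i in descriptor_matrix.index]
        X = descriptor_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(descriptor_matrix, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValidationError(f"embed_space requires n >= 4, got {n}")
    if X.shape[1] < 2:
        raise ValidationError(f"embed_space requires m >= 2 columns, got {X.shape[1]}")
    if candidate_ids is None:
        candidate_ids = [str(i) for i in range(n)]
    Z = _standardize(X, "embed_space")
    nn = min(n_neighbors, n - 1)
    reducer = umap.UMAP(
        n_components=2, n_neighbors=nn, min_dist=min_dist, random_state=seed
    )
    coords = np.asarray(reducer.fit_transform(Z), dtype=float)
    return SpaceEmbedding(
        candidate_ids=tuple(candidate_ids),
        coords=coords,
        params={"n_neighbors": nn, "min_dist": min_dist},
        seed=seed,
    )


def cluster_ward(
    features: np.ndarray | pd.DataFrame,
    k: int,
    candidate_ids: Sequence[str] | None = None,
    standardize: bool = True,
) -> Clustering:
    """Ward-linkage agglomerative clustering with canonical label numbering.

    Labels are renumbered by cluster size descending; ties by the smallest
    member index, so the labeling is a deterministic function of the input.
    """
    if isinstance(features, pd.DataFrame):
        if candidate_ids is None:
            candidate_ids = [str(i) for i in features.index]
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValidationError(f"k must lie in [1, {n}], got {k}")
    if candidate_ids is None:
        candidate_ids = [str(i) for i in range(n)]
    if standardize and X.shape[1] >= 1 and n > 1:
        X = _standardize(X, "cluster_ward")
    if k == n:
        raw = np.arange(n)
    else:
        model = AgglomerativeClustering(n_clusters=k, linkage="ward")
        raw = model.fit_predict(X)

    # canonicalize: order clusters by (-size, first member index)
    order = sorted(
        range(k),
        key=lambda lab: (-int(np.sum(raw == lab)), int(np.argmax(raw == lab))),
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = tuple(int(remap[l]) for l in raw)
    return Clustering(candidate_ids=tuple(candidate_ids), labels=labels, k=k)


def pick_representatives(
    clustering: Clustering,
    cost_rank: Mapping[str, float],
    n_per_cluster: int = 1,
) -> list[str]:
    """Cheapest ``n_per_cluster`` members of each cluster, ordered by cluster label."""
    missing = [c for c in clustering.candidate_ids if c not in cost_rank]
    if missing:
        raise ValidationError(f"cost_rank missing for candidates: {missing}")
    chosen: list[str] = []
    for label in range(clustering.k):
        members = sorted(clustering.members(label), key=lambda c: (cost_rank[c], c))
        if len(members) < n_per_cluster:
            logger.warning(
                "cluster %d has only %d members (< n_per_cluster=%d); taking all",
                label, len(members), n_per_cluster,
            )
        chosen.extend(members[:n_per_cluster])
    return chosen


def pair_across_clusters(
    bromide_clustering: Clustering,
    amine_clustering: Clustering,
    n_products: int,
    seed: int = DEFAULT_SEED,
    id_prefix: str = "P",
    id_start: int = 1,
) -> list[ProductRecord]:
    """Distinct (bromide, amine) pairs maximizing cluster-combination coverage.

    Greedy: always draw from a least-used (bromide-cluster, amine-cluster)
    combination that still has unused pairs, choosing the pair uniformly at
    random within it (seeded), so coverage counts differ by at most one while
    pairs remain available everywhere.
    """
    n_b = len(bromide_clustering.candidate_ids)
    n_a = len(amine_clustering.candidate_ids)
    if n_products < 1 or n_products > n_b * n_a:
        raise ValidationError(
            f"n_products must lie in [1, {n_b * n_a}], got {n_products}"
        )
    rng = np.random.default_rng(seed)
    pools: dict[tuple[int, int], list[tuple[str, str]]] = {}
    for b_id, b_lab in zip(bromide_clustering.candidate_ids, bromide_clustering.labels):
        for a_id, a_lab in zip(amine_clustering.candidate_ids, amine_clustering.labels):
            pools.setdefault((b_lab, a_lab), []).append((b_id, a_id))
    for combo in sorted(pools):
        rng.shuffle(pools[combo])
    usage = {combo: 0 for combo in pools}

    records: list[ProductRecord] = []
    while len(records) < n_products:
        available = [c for c in sorted(pools) if pools[c]]
        if not available:  # pragma: no cover - excluded by the precondition
            raise ValidationError("ran out of distinct pairs")
        min_use = min(usage[c] for c in available)
        choices = [c for c in available if usage[c] == min_use]
        combo = choices[int(rng.integers(len(choices)))]
        b_id, a_id = pools[combo].pop()
        usage[combo] += 1
        records.append(
            ProductRecord(
                product_id=f"{id_prefix}{id_start + len(records):03d}",
                bromide_id=b_id,
                amine_id=a_id,
            )
        )
    return records
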