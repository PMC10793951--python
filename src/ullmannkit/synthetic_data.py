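"""Seeded generator of HTE-style coupling datasets with a planted rule.

The generated tables mimic the statistical structure of a staged
Ullmann-coupling screen: a bimodal ligand Cu-L distance distribution
straddling the 2.07 A cut, substrate features straddling the amine-charge
and buried-volume cuts, yields governed by the planted three-feature rule
plus configurable label noise, ligand-free control backgrounds for a subset
of products, and a three-stage screening plan (initial panel, reselected
ligands, extension products).

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``, so regeneration is byte-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import FixedRule, predict_fixed
from .core_model import (
    OFF,
    ON,
    AmineRecord,
    BromideRecord,
    ControlResult,
    ControlType,
    LigandRecord,
    ProductRecord,
    ValidationError,
    apply_control_filter,
)

logger = logging.getLogger(__name__)

_ACTIVE_CLASSES = ("diketone", "oxalamide", "anilino_oxo_acetic_acid")


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the simulator; defaults mirror the staged-screen arithmetic
    (12 x 24 + 12 x 12 + 16 x 18 = 720 reactions, 37 products of which 9
    carry an SNAr-style background)."""

    seed: int = 42
    n_ligands_initial: int = 24
    n_ligands_reselect: int = 12
    n_products_initial: int = 12
    n_products_extension: int = 16
    n_background_products: int = 9
    n_bromides: int = 24
    n_amines: int = 12
    frac_active_ligands: float = 0.25
    label_noise: float = 0.13
    rule: FixedRule = field(default_factory=FixedRule)
    on_yield_range: tuple[float, float] = (25.0, 95.0)
    off_yield_range: tuple[float, float] = (0.0, 18.0)

    def __post_init__(self) -> None:
        for name in (
            "n_ligands_initial", "n_ligands_reselect", "n_products_initial",
            "n_products_extension", "n_background_products", "n_bromides", "n_amines",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("frac_active_ligands", "label_noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")

    @property
    def n_products_total(self) -> int:
        return self.n_products_initial + self.n_products_extension + self.n_background_products


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (open interval)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[(draw > lo) & (draw < hi)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def gen_ligands(config: SimConfig, rng: np.random.Generator) -> list[LigandRecord]:
    """Initial panel then reselected ligands; actives sit below the d cut.

    Active ligands draw d ~ N(1.95, 0.04) truncated to (1.8, 2.07) and are
    anionic; inactive ligands draw d ~ N(2.18, 0.05) truncated to
    (2.07, 2.4). The active initial ligands occupy the tail of the initial
    id range; all reselected ligands are active.
    """
    n_init = config.n_ligands_initial
    n_active = int(round(config.frac_active_ligands * n_init))
    n_inactive = n_init - n_active
    d_inactive = _trunc_normal(rng, 2.18, 0.05, 2.07, 2.40, n_inactive)
    d_active = _trunc_normal(rng, 1.95, 0.04, 1.80, 2.07, n_active + config.n_ligands_reselect)

    ligands: list[LigandRecord] = []
    for i in range(n_inactive):
        ligands.append(
            LigandRecord(
                ligand_id=f"L{i + 1:02d}",
                cu_l_distance=float(d_inactive[i]),
                ligand_class="neutral",
                charge_state="neutral",
            )
        )
    for i in range(n_active + config.n_ligands_reselect):
        ligands.append(
            LigandRecord(
                ligand_id=f"L{n_inactive + i + 1:02d}",
                cu_l_distance=float(d_active[i]),
                ligand_class=_ACTIVE_CLASSES[i % len(_ACTIVE_CLASSES)],
                charge_state="anionic",
            )
        )
    return ligands


def gen_substrates(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[BromideRecord], list[AmineRecord]]:
    """Uniformly scattered substrate features, guaranteed to straddle the
    planted thresholds whenever four or more records are drawn."""

    def _draw(n: int, lo: float, hi: float, cut: float) -> np.ndarray:
        for _ in range(1000):
            vals = rng.uniform(lo, hi, size=n)
            if n < 4 or (np.any(vals <= cut) and np.any(vals > cut)):
                return vals
        raise ValidationError("failed to straddle threshold after 1000 resamples")

    vbur = _draw(config.n_bromides, 28.0, 40.0, config.rule.vbur_max)
    n_charge = _draw(config.n_amines, -0.92, -0.70, config.rule.n_charge_max)
    bromides = [
        BromideRecord(bromide_id=f"B{i + 1:02d}", vbur=float(v)) for i, v in enumerate(vbur)
    ]
    amines = [
        AmineRecord(amine_id=f"A{i + 1:02d}", n_charge=float(c))
        for i, c in enumerate(n_charge)
    ]
    return bromides, amines


def _interleaved_selection(
    favorable: list, unfavorable: list, n: int, rng: np.random.Generator
) -> list:
    """Alternate draws from the favorable/unfavorable pools (seeded shuffles),
    falling back to whichever pool still has members."""
    fav = list(favorable)
    unf = list(unfavorable)
    rng.shuffle(fav)
    rng.shuffle(unf)
    out: list = []
    take_fav = True
    while len(out) < n:
        pool = fav if (take_fav and fav) or not unf else unf
        if not pool:
            raise ValidationError("not enough substrate records to build the product grid")
        out.append(pool.pop())
        take_fav = not take_fav
    return out


def gen_products(
    config: SimConfig,
    bromides: list[BromideRecord],
    amines: list[AmineRecord],
    rng: np.random.Generator,
) -> list[ProductRecord]:
    """Background products (P001...) then a crossed catalysis panel (P100...).

    The catalysis products form a (near-)full bromide x amine grid whose
    substrate selections interleave favorable and unfavorable records on
    each axis. Crossing makes the two substrate features orthogonal factors
    in the panel, so the planted rule is identifiable without product-level
    confounding — mirroring a screen designed to cover all four substrate
    quadrants. Cells are enumerated bromide-major, so the initial-product
    slice is itself (close to) a balanced sub-grid.
    """
    n_cat = config.n_products_initial + config.n_products_extension
    n_total = config.n_products_total
    if n_total > len(bromides) * len(amines):
        raise ValidationError(
            f"{n_total} products requested but only "
            f"{len(bromides) * len(amines)} distinct pairs exist"
        )

    rule = config.rule
    grid_pairs: list[tuple[str, str]] = []
    if n_cat > 0:
        n_a = min(len(amines), max(2, int(round(math.sqrt(n_cat / 2)))))
        n_b = min(len(bromides), math.ceil(n_cat / n_a))
        while n_b * n_a < n_cat:
            if n_a < len(amines):
                n_a += 1
            elif n_b < len(bromides):
                n_b += 1
            else:  # pragma: no cover - excluded by the pair-count check above
                raise ValidationError("cannot build a product grid of the requested size")
        fav_b = [b for b in bromides if b.vbur <= rule.vbur_max]
        unf_b = [b for b in bromides if b.vbur > rule.vbur_max]
        fav_a = [a for a in amines if a.n_charge <= rule.n_charge_max]
        unf_a = [a for a in amines if a.n_charge > rule.n_charge_max]
        sel_b = _interleaved_selection(fav_b, unf_b, n_b, rng)
        sel_a = _interleaved_selection(fav_a, unf_a, n_a, rng)
        grid_pairs = [
            (b.bromide_id, a.amine_id) for b in sel_b for a in sel_a
        ][:n_cat]

    used = set(grid_pairs)
    rest = [
        (b.bromide_id, a.amine_id)
        for b in bromides
        for a in amines
        if (b.bromide_id, a.amine_id) not in used
    ]
    if config.n_background_products > len(rest):
        raise ValidationError(
            f"{config.n_background_products} background products requested but only "
            f"{len(rest)} off-grid pairs remain"
        )
    bg_idx = rng.permutation(len(rest))[: config.n_background_products]
    background = [rest[i] for i in sorted(bg_idx)]

    products: list[ProductRecord] = []
    for i, (b, a) in enumerate(background):
        products.append(ProductRecord(product_id=f"P{i + 1:03d}", bromide_id=b, amine_id=a))
    for i, (b, a) in enumerate(grid_pairs):
        products.append(ProductRecord(product_id=f"P{100 + i}", bromide_id=b, amine_id=a))
    return products


def gen_controls(
    products: list[ProductRecord], config: SimConfig, rng: np.random.Generator
) -> list[ControlResult]:
    """Two control rows per product; the first ``n_background_products`` get a
    planted ligand-free background yield in [25, 60]."""
    if config.n_background_products > len(products):
        raise ValidationError(
            f"n_background_products={config.n_background_products} exceeds "
            f"{len(products)} products"
        )
    controls: list[ControlResult] = []
    for i, p in enumerate(products):
        if i < config.n_background_products:
            no_ligand = float(rng.uniform(25.0, 60.0))
        else:
            no_ligand = float(rng.uniform(0.0, 5.0))
        no_cu = float(rng.uniform(0.0, 2.0))
        controls.append(
            ControlResult(p.product_id, ControlType.no_ligand.value, no_ligand)
        )
        controls.append(
            ControlResult(p.product_id, ControlType.no_ligand_no_cu.value, no_cu)
        )
    return controls


def gen_design(
    config: SimConfig,
    products: list[ProductRecord],
    ligands: list[LigandRecord],
) -> pd.DataFrame:
    """Three-stage screening plan as a (product_id, ligand_id, stage) table.

    Stage 1: initial products x initial ligands. Stage 2: the same initial
    products x reselected ligands. Stage 3: extension products x (active
    initial ligands + reselected ligands). ``products`` must list the
    passing products, initial products first.
    """
    n_init_p, n_ext_p = config.n_products_initial, config.n_products_extension
    if len(products) < n_init_p + n_ext_p:
        raise ValidationError(
            f"need {n_init_p + n_ext_p} passing products, got {len(products)}"
        )
    n_init_l = config.n_ligands_initial
    if len(ligands) < n_init_l + config.n_ligands_reselect:
        raise ValidationError(
            f"need {n_init_l + config.n_ligands_reselect} ligands, got {len(ligands)}"
        )
    initial_products = products[:n_init_p]
    extension_products = products[n_init_p : n_init_p + n_ext_p]
    initial_ligands = ligands[:n_init_l]
    reselected = ligands[n_init_l : n_init_l + config.n_ligands_reselect]
    active_initial = [l for l in initial_ligands if l.cu_l_distance <= config.rule.d_max]
    stage3_panel = active_initial + list(reselected)

    rows: list[tuple[str, str, int]] = []
    for p in initial_products:
        for l in initial_ligands:
            rows.append((p.product_id, l.ligand_id, 1))
    for p in initial_products:
        for l in reselected:
            rows.append((p.product_id, l.ligand_id, 2))
    for p in extension_products:
        for l in stage3_panel:
            rows.append((p.product_id, l.ligand_id, 3))

    plan = pd.DataFrame(rows, columns=["product_id", "ligand_id", "stage"])
    if plan.duplicated(["product_id", "ligand_id"]).any():
        raise ValidationError("screening plan contains duplicate (product, ligand) pairs")
    return plan


def _ligand_quality_params(
    ligands: list[LigandRecord], rng: np.random.Generator
) -> dict[str, tuple[float, np.ndarray, float]]:
    """Per-ligand quality parameters: intrinsic strength, frequency vector, phase.

    A ligand's quality is part intrinsic (strong ligands are strong
    everywhere) and part a smooth function of standardized substrate
    coordinates, so nearby products share ligand rankings — the signal the
    nearest-neighbor recommender relies on.
    """
    params: dict[str, tuple[float, np.ndarray, float]] = {}
    for lig in ligands:
        strength = float(rng.uniform(0.0, 1.0))
        w = rng.normal(0.0, 0.8, size=2)
        phi = float(rng.uniform(0.0, 2.0 * np.pi))
        params[lig.ligand_id] = (strength, w, phi)
    return params


def gen_yields(
    plan: pd.DataFrame,
    ligands: list[LigandRecord],
    products: list[ProductRecord],
    bromides: list[BromideRecord],
    amines: list[AmineRecord],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Yields for every planned pair plus the noise-free truth table.

    The noise-free label is the planted rule's decision; the observed label
    flips with probability ``label_noise`` on average. On-labeled rows flip
    to off with an i.i.d. probability of 0.9*label_noise. Off-labeled rows
    of *active* (d below the cut) ligands flip to on ("rescues"): the
    strongest active ligands by intrinsic strength rescue at 0.6 and the
    remaining actives at a small remainder rate, with the split calibrated
    so the dataset-wide flip fraction lands at label_noise. Inactive
    ligands never flip to on — so per-ligand activity labels stay clean
    (only truly active ligands ever clear the threshold) — and the rescues
    concentrate on specific strong ligands, which makes the unexpected
    successes of off-predicted products transfer between neighboring
    products. Strength involves no substrate coordinate, so the flips
    leave the learned substrate thresholds unbiased. Yields in both label
    classes scale with the ligand's local quality, so rankings carry
    signal below the threshold.
    """
    d_by_ligand = {l.ligand_id: l.cu_l_distance for l in ligands}
    prod_by_id = {p.product_id: p for p in products}
    vbur_by_bromide = {b.bromide_id: b.vbur for b in bromides}
    charge_by_amine = {a.amine_id: a.n_charge for a in amines}

    plan_products = plan["product_id"].unique().tolist()
    coord_rows = []
    for pid in plan_products:
        p = prod_by_id[pid]
        coord_rows.append((charge_by_amine[p.amine_id], vbur_by_bromide[p.bromide_id]))
    coord_arr = np.asarray(coord_rows)
    mean = coord_arr.mean(axis=0)
    std = coord_arr.std(axis=0, ddof=0)
    std = np.where(std > 0, std, 1.0)
    z_by_product = {
        pid: (np.asarray(c) - mean) / std for pid, c in zip(plan_products, coord_rows)
    }

    quality = _ligand_quality_params(ligands, rng)
    on_lo, on_hi = config.on_yield_range
    off_lo, off_hi = config.off_yield_range

    # first pass (no randomness): noise-free labels and per-ligand counts,
    # used to calibrate rescue probabilities to the target flip rate
    true_labels: list[str] = []
    off_rows_by_ligand: dict[str, int] = {}
    n_on = 0
    for row in plan.itertuples(index=False):
        p = prod_by_id[row.product_id]
        true = predict_fixed(
            d_by_ligand[row.ligand_id],
            charge_by_amine[p.amine_id],
            vbur_by_bromide[p.bromide_id],
            config.rule,
        )
        true_labels.append(true)
        if true == ON:
            n_on += 1
        else:
            off_rows_by_ligand[row.ligand_id] = off_rows_by_ligand.get(row.ligand_id, 0) + 1

    # rescue budget: total flips should average label_noise over all rows
    p_hi = 0.6
    budget = config.label_noise * len(plan) - 0.9 * config.label_noise * n_on
    actives_by_strength = [
        l for l in sorted(ligands, key=lambda l: -quality[l.ligand_id][0])
        if l.cu_l_distance <= config.rule.d_max and off_rows_by_ligand.get(l.ligand_id, 0)
    ]
    rescue_prob = {l.ligand_id: 0.0 for l in ligands}
    if budget > 0 and actives_by_strength:
        hi_budget = 0.9 * budget
        spent = 0.0
        rescuers: list[LigandRecord] = []
        for lig in actives_by_strength:
            cost = p_hi * off_rows_by_ligand[lig.ligand_id]
            if not rescuers or spent + cost <= hi_budget:
                rescuers.append(lig)
                rescue_prob[lig.ligand_id] = p_hi
                spent += cost
            else:
                break
        rest = actives_by_strength[len(rescuers):]
        rest_rows = sum(off_rows_by_ligand[l.ligand_id] for l in rest)
        if rest_rows:
            p_lo = min(p_hi, max(0.0, (budget - spent) / rest_rows))
            for lig in rest:
                rescue_prob[lig.ligand_id] = p_lo

    reactions: list[tuple[str, str, float]] = []
    truth: list[tuple[str, str, str, str]] = []
    for row, true_label in zip(plan.itertuples(index=False), true_labels):
        strength, w, phi = quality[row.ligand_id]
        z = z_by_product[row.product_id]
        spatial = 0.5 + 0.5 * math.cos(float(w @ z) + phi)
        q = 0.65 * strength + 0.35 * spatial
        if true_label == ON:
            flip_prob = 0.9 * config.label_noise
        else:
            flip_prob = rescue_prob[row.ligand_id]
        label = true_label
        if rng.random() < min(max(flip_prob, 0.0), 0.97):
            label = OFF if label == ON else ON
        base = float(rng.uniform(0.9, 1.0))
        if label == ON and true_label == ON:
            y = on_lo + (on_hi - on_lo) * q * base
        elif label == ON:
            # rescue: clears the threshold but stays modest, as unexpected
            # successes do — it should not outrank genuinely strong ligands
            y = 21.0 + (45.0 - 21.0) * q * base
        else:
            y = off_lo + (off_hi - off_lo) * q * base
        reactions.append((row.product_id, row.ligand_id, round(y, 2)))
        truth.append((row.product_id, row.ligand_id, true_label, label))

    reactions_df = pd.DataFrame(
        reactions, columns=["product_id", "ligand_id", "yield_percent"]
    )
    truth_df = pd.DataFrame(
        truth, columns=["product_id", "ligand_id", "true_label", "observed_label"]
    )
    return reactions_df, truth_df


@dataclass
class SimDataset:
    """One simulated screen: record lists plus derived long-format tables."""

    config: SimConfig
    ligands: list[LigandRecord]
    bromides: list[BromideRecord]
    amines: list[AmineRecord]
    products: list[ProductRecord]
    controls: list[ControlResult]
    plan: pd.DataFrame
    reactions: pd.DataFrame
    truth: pd.DataFrame
    passing_products: list[ProductRecord]
    failed_products: list[ProductRecord]

    @property
    def ligands_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (l.ligand_id, l.cu_l_distance, l.ligand_class, l.charge_state)
                for l in self.ligands
            ],
            columns=["ligand_id", "cu_l_distance", "ligand_class", "charge_state"],
        )

    @property
    def bromides_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b.bromide_id, b.vbur) for b in self.bromides],
            columns=["bromide_id", "vbur"],
        )

    @property
    def amines_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.amine_id, a.n_charge) for a in self.amines],
            columns=["amine_id", "n_charge"],
        )

    @property
    def products_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.product_id, p.bromide_id, p.amine_id) for p in self.products],
            columns=["product_id", "bromide_id", "amine_id"],
        )

    @property
    def controls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.product_id, c.control_type, round(c.yield_percent, 2)) for c in self.controls],
            columns=["product_id", "control_type", "yield_percent"],
        )

    @property
    def reactions_frame(self) -> pd.DataFrame:
        return self.reactions.merge(self.plan, on=["product_id", "ligand_id"])

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in (
            ("ligands", self.ligands_frame),
            ("bromides", self.bromides_frame),
            ("amines", self.amines_frame),
            ("products", self.products_frame),
            ("reactions", self.reactions_frame),
            ("controls", self.controls_frame),
            ("truth", self.truth),
        ):
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        return written


def simulate(config: SimConfig | None = None) -> SimDataset:
    """Generate a full dataset: substrates, ligands, products, controls,
    control filtering, the staged plan, and yields — all from one seed."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    ligands = gen_ligands(config, rng)
    bromides, amines = gen_substrates(config, rng)
    products = gen_products(config, bromides, amines, rng)
    controls = gen_controls(products, config, rng)
    passing, failed = apply_control_filter(products, controls)
    plan = gen_design(config, passing, ligands)
    reactions, truth = gen_yields(plan, ligands, products, bromides, amines, config, rng)
    logger.info(
        "simulate(seed=%d): %d ligands, %d products (%d passing), %d reactions",
        config.seed, len(ligands), len(products), len(passing), len(reactions),
    )
    return SimDataset(
        config=config,
        ligands=ligands,
        bromides=bromides,
        amines=amines,
        products=products,
        controls=controls,
        plan=plan,
        reactions=reactions,
        truth=truth,
        passing_products=passing,
        failed_products=failed,
    )
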