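import numpy as np
import pandas as pd
import pytest

from ullmannkit.core_model import OFF, ON, ValidationError, apply_control_filter
from ullmannkit.classifier import predict_fixed
from ullmannkit.synthetic_data import (
    SimConfig,
    gen_controls,
    gen_design,
    gen_ligands,
    gen_products,
    gen_substrates,
    simulate,
)


@pytest.fixture
def config():
    return SimConfig(seed=11)


class TestGenLigands:
    def test_quarter_active_of_24(self, config):
        ligands = gen_ligands(config, np.random.default_rng(0))
        initial = ligands[:24]
        assert sum(l.cu_l_distance < 2.07 for l in initial) == 6

    def test_reselected_all_active_and_anionic(self, config):
        ligands = gen_ligands(config, np.random.default_rng(0))
        reselected = ligands[24:]
        assert len(reselected) == 12
        assert all(l.cu_l_distance < 2.07 for l in reselected)
        assert all(l.charge_state == "anionic" for l in reselected)

    def test_distance_bands(self, config):
        ligands = gen_ligands(config, np.random.default_rng(3))
        for l in ligands:
            if l.cu_l_distance < 2.07:
                assert 1.8 < l.cu_l_distance < 2.07
                assert l.charge_state == "anionic"
            else:
                assert 2.07 < l.cu_l_distance < 2.4
                assert l.charge_state == "neutral"

    def test_same_seed_identical(self, config):
        a = gen_ligands(config, np.random.default_rng(5))
        b = gen_ligands(config, np.random.default_rng(5))
        assert a == b

    def test_zero_active_fraction(self):
        config = SimConfig(frac_active_ligands=0.0, n_ligands_reselect=0)
        ligands = gen_ligands(config, np.random.default_rng(0))
        assert all(l.cu_l_distance > 2.07 for l in ligands)


class TestGenSubstrates:
    def test_ranges_and_straddle(self, config):
        bromides, amines = gen_substrates(config, np.random.default_rng(0))
        vb = [b.vbur for b in bromides]
        nc = [a.n_charge for a in amines]
        assert all(28 <= v <= 40 for v in vb)
        assert all(-0.92 <= c <= -0.70 for c in nc)
        assert any(v <= 33.5 for v in vb) and any(v > 33.5 for v in vb)
        assert any(c <= -0.803 for c in nc) and any(c > -0.803 for c in nc)

    def test_straddle_guaranteed_at_n4(self):
        config = SimConfig(n_bromides=4, n_amines=4)
        for seed in range(30):
            bromides, amines = gen_substrates(config, np.random.default_rng(seed))
            assert any(b.vbur <= 33.5 for b in bromides)
            assert any(b.vbur > 33.5 for b in bromides)
            assert any(a.n_charge <= -0.803 for a in amines)
            assert any(a.n_charge > -0.803 for a in amines)

    def test_single_record_no_straddle_requirement(self):
        config = SimConfig(n_bromides=1, n_amines=1)
        bromides, amines = gen_substrates(config, np.random.default_rng(0))
        assert len(bromides) == 1 and len(amines) == 1

    def test_seed_determinism(self, config):
        a = gen_substrates(config, np.random.default_rng(9))
        b = gen_substrates(config, np.random.default_rng(9))
        assert a == b


class TestGenProducts:
    def test_counts_and_distinct_pairs(self, config):
        rng = np.random.default_rng(0)
        bromides, amines = gen_substrates(config, rng)
        products = gen_products(config, bromides, amines, rng)
        assert len(products) == 37
        pairs = {(p.bromide_id, p.amine_id) for p in products}
        assert len(pairs) == 37

    def test_background_ids_come_first(self, config):
        rng = np.random.default_rng(0)
        bromides, amines = gen_substrates(config, rng)
        products = gen_products(config, bromides, amines, rng)
        assert [p.product_id for p in products[:9]] == [f"P{i:03d}" for i in range(1, 10)]
        assert products[9].product_id == "P100"

    def test_catalysis_panel_is_crossed(self, config):
        rng = np.random.default_rng(1)
        bromides, amines = gen_substrates(config, rng)
        products = gen_products(config, bromides, amines, rng)
        grid = products[9:]
        used_b = {p.bromide_id for p in grid}
        used_a = {p.amine_id for p in grid}
        # near-full grid: 28 products over a 7x4 selection
        assert len(used_b) * len(used_a) == len(grid)
        vb = {b.bromide_id: b.vbur for b in bromides}
        nc = {a.amine_id: a.n_charge for a in amines}
        assert any(vb[b] <= 33.5 for b in used_b) and any(vb[b] > 33.5 for b in used_b)
        assert any(nc[a] <= -0.803 for a in used_a) and any(nc[a] > -0.803 for a in used_a)

    def test_infeasible_count_rejected(self):
        config = SimConfig(n_bromides=2, n_amines=2, n_products_initial=3,
                           n_products_extension=3, n_background_products=0)
        rng = np.random.default_rng(0)
        bromides, amines = gen_substrates(config, rng)
        with pytest.raises(ValidationError):
            gen_products(config, bromides, amines, rng)


class TestGenControls:
    def _products(self, config, seed=0):
        rng = np.random.default_rng(seed)
        bromides, amines = gen_substrates(config, rng)
        return gen_products(config, bromides, amines, rng), rng

    def test_filter_leaves_28_of_37(self, config):
        products, rng = self._products(config)
        controls = gen_controls(products, config, rng)
        passing, failed = apply_control_filter(products, controls)
        assert len(passing) == 28 and len(failed) == 9

    def test_zero_backgrounds_all_pass(self):
        config = SimConfig(n_background_products=0)
        products, rng = self._products(config)
        controls = gen_controls(products, config, rng)
        passing, failed = apply_control_filter(products, controls)
        assert failed == []

    def test_background_yield_bands(self, config):
        products, rng = self._products(config)
        controls = gen_controls(products, config, rng)
        by_type = {}
        for c in controls:
            by_type.setdefault(c.control_type, []).append(c.yield_percent)
        assert all(y <= 2.0 for y in by_type["no_ligand_no_cu"])
        no_ligand = sorted(by_type["no_ligand"], reverse=True)
        assert all(25 <= y <= 60 for y in no_ligand[:9])
        assert all(y <= 5 for y in no_ligand[9:])

    def test_more_backgrounds_than_products_rejected(self, config):
        products, rng = self._products(config)
        bad = SimConfig(n_background_products=50)
        with pytest.raises(ValidationError):
            gen_controls(products[:10], bad, rng)


class TestGenDesign:
    def test_paper_counts_give_720_pairs(self, default_dataset):
        assert len(default_dataset.plan) == 720
        stages = default_dataset.plan.groupby("stage").size()
        assert stages[1] == 12 * 24
        assert stages[2] == 12 * 12
        assert stages[3] == 16 * 18

    def test_zero_extension_gives_432(self):
        config = SimConfig(seed=2, n_products_extension=0)
        dataset = simulate(config)
        assert len(dataset.plan) == 12 * 24 + 12 * 12

    def test_no_duplicate_pairs(self, default_dataset):
        assert not default_dataset.plan.duplicated(["product_id", "ligand_id"]).any()

    def test_stage3_panel_is_active_initials_plus_reselected(self, default_dataset):
        d_by_lig = {l.ligand_id: l.cu_l_distance for l in default_dataset.ligands}
        stage3_ligs = set(
            default_dataset.plan.loc[default_dataset.plan["stage"] == 3, "ligand_id"]
        )
        assert len(stage3_ligs) == 18
        assert all(d_by_lig[l] <= 2.07 for l in stage3_ligs)

    def test_insufficient_products_rejected(self, config):
        ligands = gen_ligands(config, np.random.default_rng(0))
        with pytest.raises(ValidationError):
            gen_design(config, [], ligands)


class TestGenYields:
    def test_noise_free_labels_equal_rule(self, noise_free_dataset):
        truth = noise_free_dataset.truth
        assert (truth["true_label"] == truth["observed_label"]).all()
        feats = noise_free_dataset.reactions.merge(
            truth, on=["product_id", "ligand_id"]
        )
        d = {l.ligand_id: l.cu_l_distance for l in noise_free_dataset.ligands}
        prod = {p.product_id: p for p in noise_free_dataset.products}
        vb = {b.bromide_id: b.vbur for b in noise_free_dataset.bromides}
        nc = {a.amine_id: a.n_charge for a in noise_free_dataset.amines}
        for row in feats.itertuples(index=False):
            p = prod[row.product_id]
            expected = predict_fixed(d[row.ligand_id], nc[p.amine_id], vb[p.bromide_id])
            assert row.true_label == expected
            observed = ON if row.yield_percent > 20 else OFF
            assert observed == row.observed_label

    def test_flip_fraction_in_binomial_band(self):
        for seed in (0, 5, 9):
            dataset = simulate(SimConfig(seed=seed))
            flipped = float(
                np.mean(dataset.truth["true_label"] != dataset.truth["observed_label"])
            )
            assert 0.10 <= flipped <= 0.16

    def test_all_unfavorable_features_all_off_at_zero_noise(self):
        config = SimConfig(seed=4, label_noise=0.0, frac_active_ligands=0.0,
                           n_ligands_reselect=0)
        rng = np.random.default_rng(4)
        ligands = gen_ligands(config, rng)
        assert all(l.cu_l_distance > 2.07 for l in ligands)
        # inactive-only panel: every reaction is off regardless of substrates
        from ullmannkit.synthetic_data import gen_yields

        bromides, amines = gen_substrates(config, rng)
        products = gen_products(config, bromides, amines, rng)
        plan = pd.DataFrame(
            [(p.product_id, l.ligand_id, 1) for p in products[9:21] for l in ligands],
            columns=["product_id", "ligand_id", "stage"],
        )
        reactions, truth = gen_yields(plan, ligands, products, bromides, amines, config, rng)
        assert (truth["observed_label"] == OFF).all()
        assert (reactions["yield_percent"] <= 20).all()

    def test_yield_ranges_match_labels(self, default_dataset):
        merged = default_dataset.reactions.merge(
            default_dataset.truth, on=["product_id", "ligand_id"]
        )
        on_rows = merged[merged["observed_label"] == ON]
        off_rows = merged[merged["observed_label"] == OFF]
        assert (on_rows["yield_percent"] > 20).all()
        assert (off_rows["yield_percent"] <= 18).all()


class TestSimulateDeterminism:
    def test_byte_identical_csv_output(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        simulate(SimConfig(seed=123)).write(a_dir)
        simulate(SimConfig(seed=123)).write(b_dir)
        for name in ("ligands", "bromides", "amines", "products", "reactions",
                     "controls", "truth"):
            assert (a_dir / f"{name}.csv").read_bytes() == (b_dir / f"{name}.csv").read_bytes()

    def test_different_seeds_differ(self):
        a = simulate(SimConfig(seed=1))
        b = simulate(SimConfig(seed=2))
        assert not a.reactions.equals(b.reactions)

    def test_schema_valid_against_core_types(self, default_dataset):
        # record lists already passed dataclass validation; spot-check frames
        assert list(default_dataset.reactions_frame.columns) == [
            "product_id", "ligand_id", "yield_percent", "stage"
        ]
        assert default_dataset.controls_frame.groupby("product_id").size().eq(2).all()

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SimConfig(label_noise=1.5)
        with pytest.raises(ValidationError):
            SimConfig(n_ligands_initial=-1)
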