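"""Kinetic model, dose-response link, and field/screen simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rush_screen.synthetic import (
    DrugEffect,
    FieldLayout,
    KineticParams,
    NoiseModel,
    WellCondition,
    dose_factor,
    retained_fraction,
    simulate_field,
    simulate_screen,
    true_class,
)

KP = KineticParams()


class TestRetainedFraction:
    def test_time_zero_with_biotin(self):
        assert retained_fraction(0, biotin=True) == pytest.approx(1 - KP.leak_fraction)

    def test_near_complete_decay_at_4h(self):
        # the biological anchor: cytoplasmic GFP is essentially gone 4 h
        # after biotin addition
        assert retained_fraction(240, biotin=True) <= 0.05

    def test_full_block_keeps_signal(self):
        # drug_factor 0 models a brefeldin-A-like complete secretion block
        assert retained_fraction(60, biotin=True, drug_factor=0.0) == pytest.approx(
            1 - KP.leak_fraction
        )

    def test_no_biotin_no_leak_is_one(self):
        kp = KineticParams(leak_fraction=0.0)
        for t in (0, 60, 240, 1000):
            assert retained_fraction(t, biotin=False, kp=kp) == 1.0

    def test_no_biotin_leak_floor(self):
        # leak saturates at the full-decay horizon
        assert retained_fraction(1000, biotin=False) == pytest.approx(1 - KP.leak_fraction)

    @pytest.mark.parametrize("t,factor", [(-1, 1), (10, -0.5)])
    def test_preconditions(self, t, factor):
        with pytest.raises(ValueError):
            retained_fraction(t, biotin=True, drug_factor=factor)

    @settings(max_examples=200, derandomize=True)
    @given(
        t1=st.floats(0, 500),
        dt=st.floats(0, 500),
        f1=st.floats(0, 10),
        df=st.floats(0, 10),
        biotin=st.booleans(),
    )
    def test_monotone_nonincreasing(self, t1, dt, f1, df, biotin):
        lo = retained_fraction(t1 + dt, biotin, f1 + df)
        hi = retained_fraction(t1, biotin, f1)
        assert lo <= hi + 1e-12
        assert 0.0 <= lo <= 1.0


class TestDoseFactor:
    def test_zero_dose_is_neutral(self):
        assert dose_factor(DrugEffect("a", f_max=4, ec50=1), 0.0) == 1.0

    def test_at_ec50(self):
        assert dose_factor(DrugEffect("a", f_max=4, ec50=1), 1.0) == pytest.approx(2.5)

    def test_saturating_inhibitor(self):
        assert dose_factor(DrugEffect("a", f_max=0, ec50=1), math.inf) == 0.0

    def test_negative_dose_raises(self):
        with pytest.raises(ValueError):
            dose_factor(DrugEffect("a"), -1.0)

    def test_invalid_effect_params(self):
        with pytest.raises(ValueError):
            DrugEffect("a", f_max=-1)
        with pytest.raises(ValueError):
            DrugEffect("a", ec50=0)
        with pytest.raises(ValueError):
            DrugEffect("a", toxicity=1.5)


class TestSimulateField:
    def test_zero_cells_pure_background(self):
        img, gt = simulate_field(WellCondition(n_cells=0), seed=1)
        assert gt.nuclei.max() == 0 and gt.cytoplasm.max() == 0
        assert gt.true_gfp == {}
        noise = NoiseModel()
        assert abs(float(img.gfp.mean()) - noise.background_level) < 20

    def test_noiseless_rendering_is_exact(self, noiseless_field):
        img, gt = noiseless_field
        for lbl, truth in gt.true_gfp.items():
            mean = img.gfp[gt.cytoplasm == lbl].mean()
            assert abs(mean - truth) <= 1.0  # rendering quantization only

    def test_same_seed_bit_identical(self):
        a, _ = simulate_field(WellCondition(n_cells=30), seed=42)
        b, _ = simulate_field(WellCondition(n_cells=30), seed=42)
        assert np.array_equal(a.dna, b.dna) and np.array_equal(a.gfp, b.gfp)

    def test_nuclei_count_and_mask_consistency(self, default_field):
        img, gt = default_field
        labels = np.unique(gt.nuclei[gt.nuclei > 0])
        assert len(labels) == 50  # requested count honoured
        assert set(labels) == set(np.unique(gt.cytoplasm[gt.cytoplasm > 0]))
        assert not np.any((gt.nuclei > 0) & (gt.cytoplasm > 0))

    def test_infeasible_density_raises(self):
        layout = FieldLayout(shape=(64, 64), n_cells=500, max_attempt_factor=5)
        with pytest.raises(RuntimeError, match="density"):
            simulate_field(WellCondition(n_cells=500), layout=layout, seed=0)

    def test_too_small_field_rejected(self):
        with pytest.raises(ValueError):
            FieldLayout(shape=(32, 32))


class TestSimulateScreen:
    def test_zero_compounds_controls_only(self):
        screen = simulate_screen([], seed=0)
        assert set(screen.platemap["role"]) == {"neg_control", "pos_control", "no_biotin"}
        assert len(screen.truth) == 0

    def test_inactive_equals_negative_control_truth(self):
        layout = FieldLayout(shape=(128, 128), n_cells=8, gfp_sigma=0.0)
        screen = simulate_screen(
            [DrugEffect("null")],
            layout=layout,
            noise=NoiseModel.noiseless(),
            seed=3,
            n_neg=2,
            n_pos=1,
            n_no_biotin=0,
        )
        by_role = {}
        for (img, gt), (_, row) in zip(screen.fields(), screen.platemap.iterrows()):
            if gt.true_gfp:
                by_role.setdefault(row["role"], set()).update(
                    round(v, 9) for v in gt.true_gfp.values()
                )
        # drug_factor is exactly 1, so true per-cell GFP matches the
        # biotin-only controls at both doses
        assert by_role["compound"] == by_role["neg_control"]

    def test_duplicate_compound_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            simulate_screen([DrugEffect("x"), DrugEffect("x")], seed=0)

    def test_each_compound_on_both_tiers(self):
        screen = simulate_screen([DrugEffect(f"c{i}") for i in range(5)], seed=0)
        comp = screen.platemap[screen.platemap["role"] == "compound"]
        tiers = comp.groupby("compound_id")["dose_tier"].agg(set)
        assert all(t == {"low", "high"} for t in tiers)

    def test_planted_truth_classes(self):
        effects = (
            [DrugEffect("a1", f_max=4), DrugEffect("a2", f_max=2)]
            + [DrugEffect("i1", f_max=0.1)]
            + [DrugEffect("t1", toxicity=0.9)]
            + [DrugEffect("n1")]
        )
        screen = simulate_screen(effects, seed=0)
        got = dict(zip(screen.truth["compound_id"], screen.truth["true_class"]))
        assert got == {
            "a1": "activator",
            "a2": "activator",
            "i1": "inhibitor",
            "t1": "toxic",
            "n1": "inactive",
        }

    def test_toxicity_reduces_cell_counts(self):
        layout = FieldLayout(n_cells=60)
        screen = simulate_screen(
            [DrugEffect("tox", toxicity=0.9), DrugEffect("null")], layout=layout, seed=7
        )
        pm = screen.platemap
        counts = {
            (row.compound_id, row.dose_tier): screen._well_conditions[
                (row.plate_id, row.well_id)
            ].n_cells
            for row in pm[pm["role"] == "compound"].itertuples(index=False)
        }
        # ~82% killed at high dose vs none for the inactive compound
        assert counts[("tox", "high")] < 0.5 * counts[("null", "high")]

    def test_fields_reiteration_is_deterministic(self):
        screen = simulate_screen([DrugEffect("c")], seed=5, n_neg=2, n_pos=1, n_no_biotin=0,
                                 layout=FieldLayout(shape=(64, 64), n_cells=4))
        first = [img.gfp.copy() for img, _ in screen.fields()]
        second = [img.gfp for img, _ in screen.fields()]
        assert all(np.array_equal(a, b) for a, b in zip(first, second))

    def test_true_class_viability_boundary(self):
        # toxic only when the expected survival at high dose crosses the gate
        assert true_class(DrugEffect("mild", toxicity=0.3)) == "inactive"
        assert true_class(DrugEffect("harsh", toxicity=0.9)) == "toxic"
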