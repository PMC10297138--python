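"""Per-cell measurement, well aggregation, and colocalization statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rush_screen.quantify import (
    CellRecord,
    pearson_colocalization,
    per_cell_intensity,
    summarize_well,
    surface_overlap,
)
from rush_screen.segmentation import LabelMaskPair
from rush_screen.synthetic import FieldLayout, NoiseModel, WellCondition, simulate_field


def _record(mean, plate="P1", well="A01", field=0):
    return CellRecord(
        plate_id=plate, well_id=well, field_index=field, cell_label=1,
        nucleus_area=50, cytoplasm_area=120, mean_cyto_gfp=mean, touches_border=False,
    )


class TestPerCellIntensity:
    def test_uniform_image(self):
        nuclei = np.zeros((20, 20), dtype=np.int32)
        cyto = np.zeros((20, 20), dtype=np.int32)
        nuclei[5:8, 5:8] = 1
        cyto[9:12, 9:12] = 1
        gfp = np.full((20, 20), 100.0)
        (rec,) = per_cell_intensity(gfp, LabelMaskPair(nuclei, cyto))
        assert rec.mean_cyto_gfp == 100.0
        assert rec.nucleus_area == 9 and rec.cytoplasm_area == 9

    def test_empty_masks_empty_list(self):
        empty = np.zeros((16, 16), dtype=np.int32)
        assert per_cell_intensity(np.zeros((16, 16)), LabelMaskPair(empty, empty)) == []

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_pixel_loop_oracle(self, seed, rng):
        # independent oracle: explicit double loop over pixels
        layout = FieldLayout(shape=(64, 64), n_cells=5)
        img, gt = simulate_field(WellCondition(n_cells=5), layout=layout, seed=seed)
        gfp = np.random.default_rng(seed).uniform(0, 5000, size=(64, 64))
        masks = LabelMaskPair(gt.nuclei, gt.cytoplasm)
        records = per_cell_intensity(gfp, masks)
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for i in range(64):
            for j in range(64):
                lbl = gt.cytoplasm[i, j]
                if lbl > 0:
                    sums[lbl] = sums.get(lbl, 0.0) + gfp[i, j]
                    counts[lbl] = counts.get(lbl, 0) + 1
        assert len(records) == len(sums)
        for rec in records:
            expected = sums[rec.cell_label] / counts[rec.cell_label]
            assert rec.mean_cyto_gfp == pytest.approx(expected, rel=1e-12)
            assert rec.cytoplasm_area == counts[rec.cell_label]

    def test_border_flag(self):
        nuclei = np.zeros((20, 20), dtype=np.int32)
        cyto = np.zeros((20, 20), dtype=np.int32)
        nuclei[0:3, 4:7] = 1   # touches top edge
        cyto[3:5, 4:7] = 1
        nuclei[10:13, 10:13] = 2
        cyto[13:15, 10:13] = 2
        recs = per_cell_intensity(np.ones((20, 20)), LabelMaskPair(nuclei, cyto))
        assert recs[0].touches_border and not recs[1].touches_border


class TestSummarizeWell:
    def test_single_cell(self):
        s = summarize_well([_record(80.0)])
        assert s.n_cells == 1 and s.well_gfp == 80.0

    def test_median_robust_to_outlier(self):
        s = summarize_well([_record(10), _record(20), _record(1000)])
        assert s.well_gfp == 20.0

    def test_counts_add_over_fields(self):
        recs = [_record(50.0, field=f) for f in range(5) for _ in range(10)]
        s = summarize_well(recs, min_cells=10)
        assert s.n_cells == 50 and s.qc_flags == set()

    def test_low_cell_count_flagged(self):
        s = summarize_well([_record(10.0)], min_cells=5)
        assert "low_cell_count" in s.qc_flags

    def test_empty_records(self):
        s = summarize_well([])
        assert s.n_cells == 0 and s.well_gfp is None
        assert "segmentation_failure" in s.qc_flags

    def test_mixed_wells_rejected(self):
        with pytest.raises(ValueError):
            summarize_well([_record(1.0, well="A01"), _record(2.0, well="B02")])


class TestPearson:
    def test_identity_is_one(self, rng):
        img = rng.uniform(0, 100, size=(32, 32))
        assert pearson_colocalization(img, img) == pytest.approx(1.0)

    def test_inverted_is_minus_one(self, rng):
        img = rng.uniform(0, 100, size=(32, 32))
        assert pearson_colocalization(img, 250.0 - img) == pytest.approx(-1.0)

    def test_orthogonal_patterns_zero(self):
        ch1 = np.array([[1.0, 0.0, 1.0, 0.0]])
        ch2 = np.array([[1.0, 1.0, 0.0, 0.0]])
        assert pearson_colocalization(ch1, ch2) == pytest.approx(0.0, abs=1e-12)

    def test_constant_channel_undefined(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_colocalization(np.ones((8, 8)), np.random.default_rng(0).random((8, 8)))

    def test_mask_restriction(self, rng):
        a = rng.uniform(0, 1, (16, 16))
        b = a.copy()
        b[8:] = rng.uniform(0, 1, (8, 16))  # decorrelate bottom half
        mask = np.zeros((16, 16), dtype=bool)
        mask[:8] = True
        assert pearson_colocalization(a, b, mask) == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        scale=st.floats(0.01, 100),
        offset=st.floats(-1000, 1000),
        seed=st.integers(0, 10_000),
    )
    def test_affine_invariance(self, scale, offset, seed):
        g = np.random.default_rng(seed)
        a = g.uniform(0, 100, size=(12, 12))
        b = g.uniform(0, 100, size=(12, 12))
        base = pearson_colocalization(a, b)
        assert pearson_colocalization(scale * a + offset, b) == pytest.approx(base, abs=1e-9)


class TestSurfaceOverlap:
    def test_identical_masks(self):
        m = np.zeros((20, 20))
        m[5:10, 5:10] = 1.0
        assert surface_overlap(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((20, 20)); a[:5] = 1.0
        b = np.zeros((20, 20)); b[10:] = 1.0
        assert surface_overlap(a, b) == 0.0

    def test_half_overlap_jaccard_third(self):
        # |A|=100, |B|=100, |A∩B|=50 -> 50/150
        a = np.zeros((30, 30)); a[0:10, 0:10] = 1.0
        b = np.zeros((30, 30)); b[5:15, 0:10] = 1.0
        assert surface_overlap(a, b, threshold_method="positive") == pytest.approx(1 / 3)

    def test_manders_m1(self):
        a = np.zeros((30, 30)); a[0:10, 0:10] = 1.0
        b = np.zeros((30, 30)); b[5:15, 0:10] = 1.0
        assert surface_overlap(a, b, threshold_method="positive", mode="manders_m1") == pytest.approx(0.5)

    def test_symmetry(self, rng):
        a = rng.uniform(0, 100, (32, 32))
        b = rng.uniform(0, 100, (32, 32))
        assert surface_overlap(a, b) == surface_overlap(b, a)

    def test_affine_rescaling_invariance(self, rng):
        a = rng.uniform(0, 100, (32, 32))
        b = rng.uniform(0, 100, (32, 32))
        assert surface_overlap(3.0 * a + 7.0, b) == pytest.approx(surface_overlap(a, b))

    def test_empty_union_raises(self):
        z = np.zeros((10, 10))
        with pytest.raises(ValueError, match="union"):
            surface_overlap(z, z, threshold_method="positive")
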