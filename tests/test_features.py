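import numpy as np
import pytest

from dosimix.features import (
    ExtractionConfig,
    build_feature_table,
    extract_features,
    feature_names,
)
from dosimix.features._discretize import discretize
from dosimix.features.texture import (
    OFFSETS_13,
    dependence_matrix,
    glcm_matrix,
    run_length_matrix,
    size_zone_matrix,
)
from dosimix.phantom import PhantomSpec, generate_phantom_case

from conftest import make_grid, make_mask


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = dict(shape=(20, 20, 12), spacing=(2.0, 2.0, 2.5),
                tumor_radius_mm=6.0, ptv_margin_mm=4.0)
    return [
        generate_phantom_case(PhantomSpec(seed=s, **spec), case_id=f"c{s}")
        for s in range(3)
    ]


class TestFeatureVector:
    def test_vector_has_105_entries_14_shape_91_other(self, small_phantom):
        from dosimix.roi import build_rois

        rois = build_rois(small_phantom)
        fv = extract_features(small_phantom.ct, rois["semiGTV"], matrix_name="CT")
        assert len(fv.values) == 105
        classes = [k.split("__")[2] for k in fv.values]
        assert classes.count("shape") == 14
        assert len(classes) - classes.count("shape") == 91

    def test_shape_block_identical_across_matrices(self, small_phantom):
        from dosimix.roi import build_rois

        roi = build_rois(small_phantom)["PTV"]
        ct_fv = extract_features(small_phantom.ct, roi, matrix_name="CT")
        dose_fv = extract_features(small_phantom.dose, roi,
                                   ExtractionConfig(n_bins=32), matrix_name="BED")
        ct_shape = [v for k, v in ct_fv.values.items() if "__shape__" in k]
        dose_shape = [v for k, v in dose_fv.values.items() if "__shape__" in k]
        np.testing.assert_array_equal(ct_shape, dose_shape)

    def test_constant_matrix_firstorder_closed_forms(self):
        vals = np.full((6, 6, 6), 42.0)
        roi = make_mask(np.ones((6, 6, 6)))
        fv = extract_features(make_grid(vals), roi, matrix_name="CT").values
        assert fv["CT__ROI__firstorder__Variance"] == 0.0
        assert fv["CT__ROI__firstorder__Mean"] == 42.0
        assert fv["CT__ROI__firstorder__Range"] == 0.0

    def test_firstorder_hand_oracle_four_voxels(self):
        vals = np.zeros((4, 4, 4))
        mask = np.zeros((4, 4, 4))
        data = [2.0, 4.0, 4.0, 10.0]
        for i, v in enumerate(data):
            vals[i, 0, 0] = v
            mask[i, 0, 0] = 1
        fv = extract_features(make_grid(vals), make_mask(mask),
                              matrix_name="CT").values
        assert fv["CT__ROI__firstorder__Mean"] == pytest.approx(5.0)
        assert fv["CT__ROI__firstorder__Minimum"] == 2.0
        assert fv["CT__ROI__firstorder__Maximum"] == 10.0
        assert fv["CT__ROI__firstorder__Energy"] == pytest.approx(
            sum(v**2 for v in data)
        )
        assert fv["CT__ROI__firstorder__Variance"] == pytest.approx(
            np.var(data)
        )

    def test_extraction_deterministic(self, small_phantom):
        from dosimix.roi import build_rois

        roi = build_rois(small_phantom)["RING"]
        a = extract_features(small_phantom.ct, roi, matrix_name="CT").values
        b = extract_features(small_phantom.ct, roi, matrix_name="CT").values
        assert a == b

    def test_empty_roi_flagged_missing(self, small_phantom):
        empty = make_mask(
            np.zeros(small_phantom.ct.shape), small_phantom.ct.spacing, "ISO50"
        )
        with pytest.warns(UserWarning):
            fv = extract_features(small_phantom.ct, empty, matrix_name="CT")
        assert fv.missing
        assert all(np.isnan(v) for v in fv.values.values())

    def test_sphere_shape_descriptors(self, small_phantom):
        from dosimix.roi import build_rois

        fv = extract_features(
            small_phantom.ct, build_rois(small_phantom)["semiGTV"],
            matrix_name="CT",
        ).values
        # spherical tumor of radius 7 mm: diameter ~14, high sphericity
        assert 0.75 < fv["CT__semiGTV__shape__Sphericity"] <= 1.05
        assert 11 < fv["CT__semiGTV__shape__Maximum3DDiameter"] < 18
        vol = 4 / 3 * np.pi * 7**3
        assert fv["CT__semiGTV__shape__VoxelVolume"] == pytest.approx(vol, rel=0.25)


class TestDiscretize:
    def test_bin_width_levels(self):
        vals = np.array([[[0.0, 24.9, 25.0, 51.0]]])
        mask = np.ones_like(vals, dtype=bool)
        g, ng = discretize(vals, mask, bin_width=25.0)
        assert list(g[mask]) == [1, 1, 2, 3]
        assert ng == 3

    def test_bin_count_covers_range(self, rng):
        vals = rng.normal(size=(5, 5, 5)) * 100
        mask = np.ones_like(vals, dtype=bool)
        g, ng = discretize(vals, mask, n_bins=32)
        assert g[mask].min() == 1 and g[mask].max() == 32

    def test_constant_roi_single_level(self):
        vals = np.full((3, 3, 3), 9.0)
        g, ng = discretize(vals, np.ones_like(vals, bool), n_bins=32)
        assert ng == 1


def _naive_glcm(levels, ng, off):
    """Triple-loop co-occurrence oracle (symmetric, normalized)."""
    P = np.zeros((ng, ng))
    nx, ny, nz = levels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                a = levels[x, y, z]
                if a == 0:
                    continue
                x2, y2, z2 = x + off[0], y + off[1], z + off[2]
                if not (0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz):
                    continue
                b = levels[x2, y2, z2]
                if b == 0:
                    continue
                P[a - 1, b - 1] += 1
                P[b - 1, a - 1] += 1
    return P / P.sum() if P.sum() else P


class TestTextureMatrices:
    def test_glcm_matches_triple_loop_oracle(self, rng):
        levels = rng.integers(0, 5, size=(5, 5, 4))  # 0 = outside ROI
        ng = 4
        for off in [(1, 0, 0), (1, -1, 0), (1, 1, 1)]:
            engine = glcm_matrix(levels, ng, off)
            oracle = _naive_glcm(levels, ng, off)
            np.testing.assert_allclose(engine, oracle, atol=1e-12)

    def test_run_length_hand_example(self):
        # one line along x: levels 1 1 2 2 2 1 -> runs (1,2),(2,3),(1,1)
        levels = np.zeros((6, 1, 1), dtype=int)
        levels[:, 0, 0] = [1, 1, 2, 2, 2, 1]
        P = run_length_matrix(levels, 2, (1, 0, 0))
        assert P[0, 1] == 1  # level 1, length 2
        assert P[1, 2] == 1  # level 2, length 3
        assert P[0, 0] == 1  # level 1, length 1
        assert P.sum() == 3

    def test_run_length_diagonal_direction(self):
        # constant 3x3x1 plane: main xy-diagonal has runs 1,2,3,2,1
        levels = np.ones((3, 3, 1), dtype=int)
        P = run_length_matrix(levels, 1, (1, 1, 0))
        assert P[0, 0] == 2  # two corner runs of length 1
        assert P[0, 1] == 2
        assert P[0, 2] == 1

    def test_size_zone_two_zones(self):
        levels = np.zeros((4, 4, 1), dtype=int)
        levels[0, 0, 0] = 1
        levels[2:4, 2:4, 0] = 1  # 4-voxel zone, 26-connected
        P = size_zone_matrix(levels, 1)
        assert P[0, 0] == 1  # one singleton zone
        assert P[0, 3] == 1  # one 4-voxel zone

    def test_dependence_counts_constant_volume(self):
        levels = np.ones((3, 3, 3), dtype=int)
        P = dependence_matrix(levels, 1)
        # center voxel has all 26 neighbors equal -> dependence j = 27
        assert P.shape[1] == 27
        assert P[0, 26] == 1


class TestFeatureTable:
    @pytest.mark.parametrize(
        "kind,n_cols",
        [("CT", 420), ("BED", 420), ("CT_BED", 840), ("COMPOSITE", 2940)],
    )
    def test_column_counts(self, tiny_cohort, kind, n_cols):
        table = build_feature_table(tiny_cohort, kind)
        assert table.data.shape == (3, n_cols)
        assert not table.data.columns.duplicated().any()

    def test_rows_ordered_by_case_id(self, tiny_cohort):
        table = build_feature_table(tiny_cohort[::-1], "CT")
        assert list(table.data.index) == sorted(c.case_id for c in tiny_cohort)

    def test_identifier_format(self):
        names = feature_names("JSD", "RING")
        assert names[0].startswith("JSD__RING__shape__")
        assert all(len(n.split("__")) == 4 for n in names)
        assert len(names) == 105
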