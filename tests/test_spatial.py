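"""Tessellation, density filtering, proportions and the Morisita-Horn index."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from morindex.errors import EmptyInputError, InvalidInputError
from morindex.spatial import (
    MorResult,
    PatientRecord,
    PolygonCounts,
    compute_proportions,
    filter_low_density,
    morisita_horn,
    morisita_horn_from_counts,
    stratify_patients,
    tessellate_counts,
)


def make_counts(n_immune, n_tumor, area=1024 * 1024, n_extra=None):
    n_immune = np.asarray(n_immune)
    n_tumor = np.asarray(n_tumor)
    n = len(n_immune)
    total = n_immune + n_tumor + (np.zeros(n, dtype=int) if n_extra is None else n_extra)
    return PolygonCounts(
        row=np.zeros(n, dtype=int),
        col=np.arange(n),
        area_px=np.full(n, area),
        n_immune=n_immune,
        n_tumor=n_tumor,
        n_total=total,
    )


class TestTessellation:
    def test_full_mask_partitions_into_h_squares(self):
        counts = tessellate_counts([], [], np.ones((2048, 2048), bool), h_px=1024)
        assert len(counts) == 4
        assert np.all(counts.area_px == 1024 * 1024)

    def test_half_open_cells_assign_centroids_uniquely(self):
        mask = np.ones((2048, 2048), bool)
        counts = tessellate_counts(
            [(0.0, 0.0), (1030.0, 10.0)], ["immune", "tumor"], mask, h_px=1024
        )
        df = counts.to_dataframe().set_index(["polygon_row", "polygon_col"])
        assert df.loc[(0, 0), "n_immune"] == 1 and df.loc[(0, 0), "n_tumor"] == 0
        assert df.loc[(1, 0), "n_tumor"] == 1 and df.loc[(1, 0), "n_immune"] == 0

    def test_boundary_centroid_falls_into_second_row(self):
        mask = np.ones((2048, 1024), bool)
        counts = tessellate_counts([(1024.0, 5.0)], ["tumor"], mask, h_px=1024)
        df = counts.to_dataframe().set_index("polygon_row")
        assert df.loc[1, "n_tumor"] == 1
        assert df.loc[0, "n_tumor"] == 0

    def test_grid_anchored_at_mask_bounding_box(self):
        mask = np.zeros((300, 300), bool)
        mask[100:228, 100:228] = True  # bbox origin (100, 100)
        counts = tessellate_counts([(110.0, 110.0)], ["immune"], mask, h_px=64)
        df = counts.to_dataframe()
        assert df["d_px"].sum() == 128 * 128
        at_origin = df[(df.polygon_row == 0) & (df.polygon_col == 0)].iloc[0]
        assert at_origin["n_immune"] == 1

    def test_partial_edge_cells_use_clipped_tissue_area(self):
        mask = np.ones((100, 64), bool)  # 100 rows: second cell row is partial
        counts = tessellate_counts([], [], mask, h_px=64)
        areas = sorted(counts.area_px.tolist())
        assert areas == [36 * 64, 64 * 64]

    def test_empty_mask_yields_empty_counts(self):
        counts = tessellate_counts([(1.0, 1.0)], ["tumor"], np.zeros((64, 64), bool))
        assert len(counts) == 0


class TestDensityFilter:
    def test_boundary_of_printed_rule(self):
        # 209 / 1024^2 is just below the 0.0002 threshold, 210 just above
        counts = make_counts([209, 210], [0, 0])
        out = filter_low_density(counts, tau=0.0002)
        assert out.included.tolist() == [False, True]

    def test_zero_count_polygon_always_excluded(self):
        out = filter_low_density(make_counts([0, 5000], [0, 0]))
        assert out.included.tolist() == [False, True]

    def test_counts_unmodified_by_filter(self):
        counts = make_counts([1, 2], [3, 4])
        out = filter_low_density(counts)
        assert np.array_equal(out.n_immune, counts.n_immune)
        assert np.array_equal(out.area_px, counts.area_px)


class TestProportions:
    def test_normalization(self):
        props = compute_proportions(make_counts([3, 1], [1, 3]))
        assert np.allclose(props.p_immune, [0.75, 0.25])
        assert np.allclose(props.p_tumor, [0.25, 0.75])

    def test_absent_population_is_undefined_not_zero(self):
        props = compute_proportions(make_counts([0, 0], [1, 3]))
        assert props.p_immune is None
        assert not props.defined

    def test_sums_run_over_included_polygons_only(self):
        counts = make_counts([10, 10, 80], [10, 10, 80])
        counts.included[2] = False
        props = compute_proportions(counts)
        assert np.allclose(props.p_immune, [0.5, 0.5])

    def test_no_included_polygons_is_an_error(self):
        counts = make_counts([1], [1], n_extra=None)
        counts.included[:] = False
        with pytest.raises(EmptyInputError):
            compute_proportions(counts)


class TestMorisitaHorn:
    def test_disjoint_supports_give_exactly_zero(self):
        res = morisita_horn_from_counts(make_counts([10, 0], [0, 10]))
        assert res.value == 0.0

    def test_identical_distributions_give_exactly_one(self):
        res = morisita_horn_from_counts(make_counts([5, 5], [7, 7]))
        assert res.value == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_example(self):
        # p_l=[.75,.25], p_c=[.25,.75]: 2*(0.1875+0.1875)/(0.625+0.625)=0.6
        res = morisita_horn_from_counts(make_counts([3, 1], [1, 3]))
        assert res.value == pytest.approx(0.6, abs=1e-12)

    def test_undefined_when_population_absent(self):
        res = morisita_horn_from_counts(make_counts([0, 0], [1, 3]))
        assert res.value is None and not res.defined

    @given(
        st.integers(2, 12).flatmap(
            lambda n: st.tuples(
                st.lists(st.integers(0, 500), min_size=n, max_size=n),
                st.lists(st.integers(0, 500), min_size=n, max_size=n),
            )
        )
    )
    def test_index_properties(self, pair):
        imm, tum = np.array(pair[0]), np.array(pair[1])
        res = morisita_horn_from_counts(make_counts(imm, tum))
        if res.value is None:
            assert imm.sum() == 0 or tum.sum() == 0
            return
        assert 0.0 <= res.value <= 1.0
        # symmetry under swapping the two populations
        swapped = morisita_horn_from_counts(make_counts(tum, imm))
        assert swapped.value == pytest.approx(res.value, abs=1e-12)
        # invariance to scaling one population
        scaled = morisita_horn_from_counts(make_counts(imm * 7, tum))
        assert scaled.value == pytest.approx(res.value, abs=1e-12)
        # permutation equivariance
        perm = np.random.default_rng(0).permutation(len(imm))
        permuted = morisita_horn_from_counts(make_counts(imm[perm], tum[perm]))
        assert permuted.value == pytest.approx(res.value, abs=1e-12)


class TestStratification:
    def records(self, values):
        return [PatientRecord(f"p{i}", v) for i, v in enumerate(values)]

    def test_median_split(self):
        out = stratify_patients(self.records([0.1, 0.2, 0.3, 0.4]))
        assert [r.group for r in out] == ["low", "low", "high", "high"]

    def test_all_identical_values_warn_and_go_low(self):
        with pytest.warns(UserWarning):
            out = stratify_patients(self.records([0.5, 0.5, 0.5]))
        assert all(r.group == "low" for r in out)

    def test_upper_quartile_cutoff(self):
        # numpy linear interpolation: 75% quantile of [1,2,3,4] is 3.25
        out = stratify_patients(self.records([1, 2, 3, 4]), quantile=0.75)
        assert sum(r.group == "high" for r in out) == 1
        assert out[3].group == "high"

    def test_undefined_values_left_ungrouped(self):
        recs = self.records([0.1, 0.9]) + [PatientRecord("px", None)]
        out = stratify_patients(recs)
        assert out[2].group is None

    def test_all_undefined_is_an_error(self):
        with pytest.raises(EmptyInputError):
            stratify_patients([PatientRecord("a", None), PatientRecord("b", None)])


class TestPolygonCountsValidation:
    def test_total_must_cover_class_counts(self):
        with pytest.raises(InvalidInputError):
            PolygonCounts(
                row=[0, 0], col=[0, 1], area_px=[10, 10],
                n_immune=[5, 0], n_tumor=[5, 0], n_total=[5, 0],
            )

    def test_nonpositive_area_rejected(self):
        with pytest.raises(InvalidInputError):
            PolygonCounts(
                row=[0], col=[0], area_px=[0],
                n_immune=[0], n_tumor=[0], n_total=[0],
            )
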