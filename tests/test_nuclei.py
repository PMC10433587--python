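"""Stain deconvolution, Bernsen thresholding, watershed and classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import bernsen_bruteforce
from morindex.errors import InvalidInputError, InvalidStateError
from morindex.fixtures import NucleusSpec, render_ihc_patch
from morindex.nuclei import (
    LabeledNuclei,
    bernsen_mask,
    classify_nuclei,
    count_nuclei,
    dab_to_8bit,
    deconvolve_stains,
    segment_nuclei_watershed,
)


class TestDeconvolution:
    def test_white_patch_has_zero_absorbance(self):
        ch = deconvolve_stains(np.full((8, 8, 3), 255, dtype=np.uint8))
        assert np.all(ch.hematoxylin_od == 0.0)
        assert np.all(ch.dab_od == 0.0)

    def test_black_patch_hits_the_od_cap(self):
        ch = deconvolve_stains(np.zeros((8, 8, 3), dtype=np.uint8), od_cap=3.0)
        assert np.all(ch.hematoxylin_od == 3.0)
        assert np.all(ch.dab_od == 3.0)

    def test_round_trip_with_renderer(self):
        # a DAB-only patch must unmix into DAB with no hematoxylin leakage
        spec = NucleusSpec((64.0, 64.0), (8.0, 6.0), 45.0, "immune")
        patch, truth = render_ihc_patch([spec], (128, 128), 0.0, 0, texture=False)
        ch = deconvolve_stains(patch)
        inside = truth.instance_raster == 1
        assert ch.dab_od[inside].min() > 0.5
        assert np.abs(ch.hematoxylin_od[inside]).max() < 0.05
        assert np.abs(ch.dab_od[~inside]).max() < 0.05

    def test_rejects_non_rgb_input(self):
        with pytest.raises(InvalidInputError):
            deconvolve_stains(np.zeros((8, 8)))


class TestBernsen:
    def test_constant_image_is_all_background(self):
        assert not bernsen_mask(np.full((100, 100), 170.0), 77, 15).any()

    def test_step_image_thresholds_at_midrange(self):
        img = np.zeros((9, 9))
        img[:, 4:] = 200.0
        out = bernsen_mask(img, 9, 15)
        assert np.array_equal(out, bernsen_bruteforce(img, 9, 15))
        # bright-side pixels whose window sees the step exceed the midrange;
        # the rightmost column's (reflected) window is all-200, zero contrast
        assert out[:, 4:8].all()
        assert not out[:, :4].any()
        assert not out[:, 8].any()

    def test_local_bump_on_low_contrast_background(self):
        img = np.full((32, 32), 100.0)
        img[14:17, 14:17] = 120.0
        out = bernsen_mask(img, 9, 15)
        assert np.array_equal(out, img == 120.0)

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(InvalidInputError):
            bernsen_mask(np.zeros((32, 32)), 77, 15)

    @pytest.mark.parametrize("window", [2, 1, -3])
    def test_even_or_tiny_windows_rejected(self, window):
        with pytest.raises(InvalidInputError):
            bernsen_mask(np.zeros((32, 32)), window, 15)

    @given(
        st.integers(0, 2**31 - 1),
        st.sampled_from([16, 24, 33, 64]),
        st.sampled_from([3, 5, 7, 9, 13]),
    )
    def test_matches_bruteforce_oracle(self, seed, size, window):
        img = np.random.default_rng(seed).integers(0, 256, (size, size))
        fast = bernsen_mask(img, window, 15)
        assert np.array_equal(fast, bernsen_bruteforce(img, window, 15))


class TestWatershed:
    def test_blank_patch_yields_no_instances(self):
        patch, _ = render_ihc_patch([], (128, 128), 0.0, 0)
        out = segment_nuclei_watershed(deconvolve_stains(patch))
        assert out.n_instances == 0

    def test_non_touching_nuclei_counted_exactly(self):
        rng = np.random.default_rng(1)
        specs = []
        for r in range(3):
            for c in range(10):
                specs.append(
                    NucleusSpec(
                        (40.0 + 60 * r, 20.0 + 22 * c),
                        (rng.uniform(5.5, 7.0), rng.uniform(4.0, 5.0)),
                        rng.uniform(0, 180),
                        "stroma",
                    )
                )
        patch, _ = render_ihc_patch(specs, (256, 256), 0.0, 0, texture=False)
        out = segment_nuclei_watershed(deconvolve_stains(patch))
        assert out.n_instances == 30

    def test_touching_pair_split_by_watershed(self):
        specs = [
            NucleusSpec((64.0, 58.0), (7.0, 7.0), 0.0, "stroma"),
            NucleusSpec((64.0, 70.0), (7.0, 7.0), 0.0, "stroma"),
        ]
        patch, _ = render_ihc_patch(specs, (128, 128), 0.0, 0, texture=False)
        out = segment_nuclei_watershed(deconvolve_stains(patch))
        assert out.n_instances == 2

    def test_min_area_filter_drops_specks(self):
        specs = [NucleusSpec((64.0, 64.0), (3.0, 3.0), 0.0, "stroma")]
        patch, _ = render_ihc_patch(specs, (128, 128), 0.0, 0, texture=False)
        out = segment_nuclei_watershed(deconvolve_stains(patch), min_area_px=40)
        assert out.n_instances == 0

    def test_deterministic(self, rendered_study):
        _, patch, _ = rendered_study
        a = segment_nuclei_watershed(deconvolve_stains(patch))
        b = segment_nuclei_watershed(deconvolve_stains(patch))
        assert np.array_equal(a.instance_raster, b.instance_raster)


def synthetic_instances():
    raster = np.zeros((32, 32), dtype=np.int32)
    raster[4:10, 4:10] = 1  # 36 px
    raster[20:26, 4:10] = 2
    raster[12:18, 20:26] = 3
    return LabeledNuclei.from_raster(raster)


class TestClassification:
    def test_priority_immune_over_tumor_over_stroma(self):
        nuclei = synthetic_instances()
        epithelium = np.zeros((32, 32), bool)
        epithelium[:, :16] = True  # instances 1 and 2 have centroids here
        immune = np.zeros((32, 32), bool)
        immune[4:10, 4:10] = True  # instance 1 fully DAB-positive
        out = classify_nuclei(nuclei, epithelium, immune)
        by_id = {r.instance_id: r.cls for r in out.records}
        assert by_id == {1: "immune", 2: "tumor", 3: "stroma"}

    def test_overlap_fraction_threshold(self):
        nuclei = synthetic_instances()
        immune = np.zeros((32, 32), bool)
        immune[4:10, 4:7] = True  # exactly half of instance 1
        out = classify_nuclei(nuclei, np.zeros((32, 32), bool), immune,
                              immune_overlap_frac=0.5)
        assert out.records[0].cls == "immune"
        out = classify_nuclei(nuclei, np.zeros((32, 32), bool), immune,
                              immune_overlap_frac=0.6)
        assert out.records[0].cls == "stroma"

    def test_class_partition_is_exhaustive(self, rendered_study):
        _, patch, _ = rendered_study
        from morindex.epithelium import segment_epithelium

        ch = deconvolve_stains(patch)
        nuc = segment_nuclei_watershed(ch)
        out = classify_nuclei(
            nuc, segment_epithelium(patch), bernsen_mask(dab_to_8bit(ch.dab_od))
        )
        n_t, n_i, n_s = count_nuclei(out)
        assert n_t + n_i + n_s == out.n_instances

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_nuclei(
                synthetic_instances(), np.zeros((16, 16), bool), np.zeros((32, 32), bool)
            )

    def test_counting_requires_classified_input(self):
        with pytest.raises(InvalidStateError):
            count_nuclei(synthetic_instances())

    def test_counts_by_class(self):
        nuclei = synthetic_instances()
        out = classify_nuclei(
            nuclei, np.zeros((32, 32), bool), np.zeros((32, 32), bool)
        )
        assert count_nuclei(out) == (0, 0, 3)
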