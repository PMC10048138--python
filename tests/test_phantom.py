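"""Phantom generator: geometry, imbalance, cohorts, frequencies."""

import dataclasses

import numpy as np
import pytest

from myinet.phantom import (LabeledImage, PhantomParams, class_frequencies,
                            generate_cohort, generate_phantom)


class TestGeneratePhantom:
    def test_zero_extent_wedge_has_no_lge(self, small_params):
        params = dataclasses.replace(small_params,
                                     lge_angular_extent_range=(0.0, 0.0))
        im = generate_phantom(params, seed=3)
        assert set(np.unique(im.labels)) == {0, 1, 2}

    def test_seeded_determinism(self, small_params):
        a = generate_phantom(small_params, seed=7)
        b = generate_phantom(small_params, seed=7)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_imbalance_ordering_holds_for_most_seeds(self, small_params):
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            counts = np.bincount(generate_phantom(small_params, seed).labels.ravel(),
                                 minlength=4)
            ok += bool(counts[0] > counts[1] > counts[2] > counts[3])
        assert ok >= 0.95 * n_seeds

    def test_labels_recomputable_from_geometry(self):
        # with zero noise the label of every pixel is a pure function of its
        # polar coordinates; regenerate them from the same sampled geometry
        params = PhantomParams.default(64)
        params = dataclasses.replace(params, noise_sd=0.0)
        im = generate_phantom(params, seed=21)
        # recover geometry by replaying the generator's draw order
        rng = np.random.default_rng(21)
        cx = 32 + rng.uniform(-params.center_jitter, params.center_jitter)
        cy = 32 + rng.uniform(-params.center_jitter, params.center_jitter)
        rb = rng.uniform(*params.blood_radius_range)
        thick = rng.uniform(*params.myocardium_thickness_range)
        wedge_start = rng.uniform(0.0, 360.0)
        wedge_extent = rng.uniform(*params.lge_angular_extent_range)
        trans = rng.uniform(*params.lge_transmurality_range)
        yy, xx = np.mgrid[0:64, 0:64]
        r = np.hypot(xx - cx, yy - cy)
        theta = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
        expected = np.zeros((64, 64), dtype=int)
        expected[r < rb] = 1
        wall = (r >= rb) & (r < rb + thick)
        expected[wall] = 2
        wedge = wall & (((theta - wedge_start) % 360.0) < wedge_extent)
        expected[wedge & (r < rb + trans * thick)] = 3
        np.testing.assert_array_equal(im.labels, expected)

    def test_invalid_params_rejected(self):
        params = PhantomParams(image_size=64)  # 256-scale radii in a 64 image
        with pytest.raises(ValueError):
            generate_phantom(params, seed=0)
        bad = dataclasses.replace(PhantomParams.default(64), mvo_probability=1.5)
        with pytest.raises(ValueError):
            generate_phantom(bad, seed=0)

    def test_pixels_in_unit_interval(self, small_phantom):
        assert small_phantom.pixels.min() >= 0.0
        assert small_phantom.pixels.max() <= 1.0

    def test_scar_is_hyperintense_and_muscle_nulled(self, small_params):
        params = dataclasses.replace(small_params, noise_sd=0.0,
                                     background_gradient_amplitude=0.0)
        im = generate_phantom(params, seed=2)
        if (im.labels == 3).any():
            assert im.pixels[im.labels == 3].mean() > im.pixels[im.labels == 2].mean()
        assert im.pixels[im.labels == 1].mean() > im.pixels[im.labels == 2].mean()


class TestCohort:
    def test_split_counts_and_arithmetic(self, small_params):
        cohort = generate_cohort(10, 3, small_params, seed=0)
        assert len(cohort.images) == 30
        by_split = {s: [p for p, v in cohort.split_assignment.items() if v == s]
                    for s in ("train", "validation", "test")}
        assert sorted(len(v) for v in by_split.values()) == [2, 2, 6]
        assert len(by_split["train"]) == 6

    def test_patient_sets_disjoint_across_splits(self, small_params):
        cohort = generate_cohort(9, 2, small_params, seed=4)
        seen = {}
        for im in cohort.images:
            split = cohort.split_assignment[im.patient_id]
            assert seen.setdefault(im.patient_id, split) == split
        splits = set(cohort.split_assignment.values())
        assert splits == {"train", "validation", "test"}

    def test_too_few_patients_rejected(self, small_params):
        with pytest.raises(ValueError):
            generate_cohort(4, 2, small_params, seed=0)

    def test_cohort_determinism(self, small_params):
        a = generate_cohort(6, 2, small_params, seed=9)
        b = generate_cohort(6, 2, small_params, seed=9)
        assert a.split_assignment == b.split_assignment
        for x, y in zip(a.images, b.images):
            np.testing.assert_array_equal(x.pixels, y.pixels)

    def test_lge_fraction_is_small(self, small_params):
        # severe imbalance: scar well under 5% of all pixels
        cohort = generate_cohort(30, 2, small_params, seed=1)
        freqs = class_frequencies(cohort.images)
        assert freqs[3] < 0.05
        assert freqs[0] > freqs[1] > freqs[2] > freqs[3]


class TestClassFrequencies:
    def test_equal_counts(self):
        im = LabeledImage(np.zeros((2, 2)), np.array([[0, 1], [2, 3]]))
        np.testing.assert_allclose(class_frequencies([im]), [0.25] * 4)

    def test_hand_counted(self):
        im = LabeledImage(np.zeros((2, 2)), np.array([[0, 0], [0, 1]]))
        np.testing.assert_allclose(class_frequencies([im]), [0.75, 0.25, 0, 0])

    def test_matches_brute_force_counting_and_sums_to_one(self, small_params):
        images = [generate_phantom(small_params, s) for s in range(20)]
        freqs = class_frequencies(images)
        flat = np.concatenate([im.labels.ravel() for im in images])
        brute = np.array([(flat == c).sum() for c in range(4)]) / flat.size
        np.testing.assert_array_equal(freqs, brute)
        assert freqs.sum() == 1.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            class_frequencies([])
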