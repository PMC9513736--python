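import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from ccrings import (
    CohortSpec,
    PhantomConfigError,
    PhantomSpec,
    generate_paired_cohort,
    generate_phantom,
    split_deficits,
)

S8 = np.ones((3, 3), dtype=bool)


class TestPhantomGeneration:
    def test_determinism(self, fast_spec):
        a1, s1, t1 = generate_phantom(fast_spec)
        a2, s2, t2 = generate_phantom(fast_spec)
        np.testing.assert_array_equal(a1.pixels, a2.pixels)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        np.testing.assert_array_equal(t1.deficit_mask, t2.deficit_mask)
        assert t1.ring_truth_fractions == t2.ring_truth_fractions

    def test_zero_deficit_case(self, fast_spec):
        spec = dataclasses.replace(
            fast_spec, ring_fd_fraction=(0.0,) * 5, background_fd_fraction=0.0,
            speckle_sigma=0.0,
        )
        _, _, truth = generate_phantom(spec)
        assert not truth.deficit_mask.any()
        assert truth.ring_truth_fractions == (0.0,) * 5

    def test_saturation_case(self, fast_spec):
        spec = dataclasses.replace(fast_spec, ring_fd_fraction=(1.0,) * 5)
        _, _, truth = generate_phantom(spec)
        assert truth.ring_truth_fractions == (1.0,) * 5
        for k in range(1, 6):
            zone = truth.ring_zone_map == k
            assert truth.deficit_mask[zone].all()

    def test_realized_fractions_match_design_by_pixel_count(self):
        fractions = (0.52, 0.51, 0.50, 0.49, 0.48)
        spec = PhantomSpec(seed=42, ring_fd_fraction=fractions)
        _, _, truth = generate_phantom(spec)
        for k in range(5):
            zone = truth.ring_zone_map == k + 1
            counted = truth.deficit_mask[zone].sum() / zone.sum()  # independent count
            assert counted == pytest.approx(truth.ring_truth_fractions[k])
            assert abs(counted - fractions[k]) < 0.02

    def test_component_counts_match_independent_labeling(self, fast_spec):
        _, _, truth = generate_phantom(fast_spec)
        for k in range(5):
            zone = truth.ring_zone_map == k + 1
            _, n = ndimage.label(truth.deficit_mask & zone, structure=S8)
            assert truth.component_count_per_ring[k] == n

    def test_geometry_masks_disjoint_and_nested(self, fast_spec):
        _, _, truth = generate_phantom(fast_spec)
        assert not (truth.mnv_mask & truth.halo_mask).any()
        # halo strictly surrounds the MNV: dilated MNV stays inside MNV|halo
        dilated = ndimage.binary_dilation(truth.mnv_mask, structure=S8)
        assert (dilated & ~truth.mnv_mask & ~truth.halo_mask).sum() == 0
        assert not (truth.deficit_mask & (truth.mnv_mask | truth.halo_mask)).any()

    def test_default_geometry_keeps_mnv_margin(self):
        _, _, truth = generate_phantom(PhantomSpec(seed=0))
        rows, cols = np.nonzero(truth.mnv_mask)
        pitch = PhantomSpec().pixel_pitch_um
        margin_px = min(rows.min(), cols.min(), 499 - rows.max(), 499 - cols.max())
        assert margin_px * pitch >= 1000.0

    def test_infeasible_geometry_raises_named_error(self):
        with pytest.raises(PhantomConfigError, match="margin"):
            PhantomSpec(mnv_radius_um=600.0)
        with pytest.raises(PhantomConfigError, match="rings do not fit"):
            PhantomSpec(mnv_radius_um=400.0, halo_width_um=200.0)
        with pytest.raises(PhantomConfigError, match="fraction"):
            PhantomSpec(ring_fd_fraction=(0.5, 0.5, 0.5, 0.5, 1.5))

    def test_shadow_attenuates_both_images(self, fast_spec):
        spec = dataclasses.replace(
            fast_spec, speckle_sigma=0.0, shadow_strength=0.5, vessel_count=1,
            vessel_width_um=240.0,
        )
        angio, struct, truth = generate_phantom(spec)
        stripe = truth.vessel_mask
        flow = ~truth.deficit_mask & ~(truth.mnv_mask | truth.halo_mask)
        assert angio.pixels[stripe & flow].mean() == pytest.approx(
            0.5 * angio.pixels[~stripe & flow].mean(), rel=0.02
        )
        assert struct.pixels[stripe].mean() == pytest.approx(
            0.5 * struct.pixels[~stripe].mean(), rel=0.02
        )


class TestSplitDeficits:
    def test_identity_and_validation(self, rng):
        mask = rng.random((40, 40)) < 0.2
        np.testing.assert_array_equal(split_deficits(mask, 1), mask)
        with pytest.raises(ValueError):
            split_deficits(mask, 0.5)

    def test_square_splits_into_two_near_halves(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        out = split_deficits(mask, 2)
        labels, n = ndimage.label(out, structure=S8)
        sizes = np.sort(np.bincount(labels.ravel())[1:])
        assert n == 2
        assert sizes.min() >= 170 and sizes.max() <= 210
        assert sizes.sum() >= 0.95 * 400

    def test_fifty_discs_double_to_about_hundred(self):
        radius = 10
        yy, xx = np.mgrid[:600, :600]
        mask = np.zeros((600, 600), dtype=bool)
        rng = np.random.default_rng(3)
        placed = 0
        while placed < 50:
            cy, cx = rng.integers(30, 570, 2)
            disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
            if not (mask & ndimage.binary_dilation(disc, iterations=2)).any():
                mask |= disc
                placed += 1
        out = split_deficits(mask, 2, rng=7)
        _, n = ndimage.label(out, structure=S8)
        assert abs(n - 100) <= 5
        # only one-pixel separator lines removed: at most a diameter per disc
        assert int(mask.sum()) - int(out.sum()) <= 50 * (2 * radius + 1)

    def test_fractional_factor_scales_expected_count(self):
        yy, xx = np.mgrid[:400, :400]
        mask = np.zeros((400, 400), dtype=bool)
        for cy in range(20, 400, 40):
            for cx in range(20, 400, 40):
                mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= 25
        _, n0 = ndimage.label(mask, structure=S8)
        out = split_deficits(mask, 1.5, rng=11)
        _, n1 = ndimage.label(out, structure=S8)
        assert n1 / n0 == pytest.approx(1.5, abs=0.15)


class TestPairedCohort:
    def test_null_cohort_has_identical_truths(self, fast_spec):
        cohort = CohortSpec(
            n_eyes=2, t1_spec=fast_spec, fd_percent_delta_per_ring=(0.0,) * 5,
            split_factor=1.0, between_eye_sd=0.0, seed=3,
        )
        for rec in generate_paired_cohort(cohort, render=False):
            np.testing.assert_array_equal(
                rec.t1[2].deficit_mask, rec.t2[2].deficit_mask
            )
            assert rec.t1[2].ring_truth_fractions == rec.t2[2].ring_truth_fractions

    def test_split_two_doubles_counts_and_conserves_area(self, fast_spec):
        # sparse ~40 px deficits: components stay isolated, so the doubling
        # mechanism is visible without merge/fragment noise
        spec = dataclasses.replace(
            fast_spec, deficit_mean_area_um2=5760.0,
            ring_fd_fraction=(0.2,) * 5, background_fd_fraction=0.2,
        )
        cohort = CohortSpec(
            n_eyes=3, t1_spec=spec, fd_percent_delta_per_ring=(0.0,) * 5,
            split_factor=2.0, between_eye_sd=0.0, seed=5,
        )
        for rec in generate_paired_cohort(cohort, render=False):
            t1, t2 = rec.t1[2], rec.t2[2]
            for k in range(5):
                zone = t1.ring_zone_map == k + 1
                a1 = int((t1.deficit_mask & zone).sum())
                a2 = int((t2.deficit_mask & zone).sum())
                assert abs(a2 - a1) <= 0.01 * a1
                ratio = t2.component_count_per_ring[k] / t1.component_count_per_ring[k]
                assert 1.8 <= ratio <= 2.2

    def test_realized_deltas_track_design(self):
        """Realized T2-T1 fraction changes follow the designed deltas: with no
        eye-level noise the cohort mean matches the deltas to rasterization
        precision, and with noise each eye matches its own designed draw."""
        spec = PhantomSpec(deficit_mean_area_um2=1440.0)
        deltas = (-2.0, -3.1, -3.6, -3.5, -3.2)
        cohort = CohortSpec(
            n_eyes=10, t1_spec=spec, fd_percent_delta_per_ring=deltas,
            split_factor=1.0, between_eye_sd=0.0, seed=7,
        )
        records = generate_paired_cohort(cohort, render=False)
        realized = np.array([r.realized_delta_points for r in records])
        np.testing.assert_allclose(realized.mean(axis=0), deltas, atol=0.1)

        noisy = CohortSpec(
            n_eyes=10, t1_spec=spec, fd_percent_delta_per_ring=deltas,
            split_factor=1.0, between_eye_sd=2.0, seed=7,
        )
        for rec in generate_paired_cohort(noisy, render=False):
            np.testing.assert_allclose(
                rec.realized_delta_points, rec.designed_delta_points, atol=0.1
            )

    def test_same_geometry_reused_at_t2(self, fast_spec):
        cohort = CohortSpec(n_eyes=2, t1_spec=fast_spec, seed=9)
        for rec in generate_paired_cohort(cohort, render=False):
            np.testing.assert_array_equal(rec.t1[2].mnv_mask, rec.t2[2].mnv_mask)
            np.testing.assert_array_equal(rec.t1[2].halo_mask, rec.t2[2].halo_mask)
            np.testing.assert_array_equal(rec.t1[2].vessel_mask, rec.t2[2].vessel_mask)

    def test_cohort_determinism_and_render_invariance(self, fast_spec):
        cohort = CohortSpec(n_eyes=2, t1_spec=fast_spec, seed=13)
        r1 = generate_paired_cohort(cohort, render=False)
        r2 = generate_paired_cohort(cohort, render=True)
        for a, b in zip(r1, r2):
            np.testing.assert_array_equal(a.t1[2].deficit_mask, b.t1[2].deficit_mask)
            np.testing.assert_array_equal(a.t2[2].deficit_mask, b.t2[2].deficit_mask)
        r3 = generate_paired_cohort(cohort, render=True)
        for a, b in zip(r2, r3):
            np.testing.assert_array_equal(a.t1[0].pixels, b.t1[0].pixels)
            np.testing.assert_array_equal(a.t2[0].pixels, b.t2[0].pixels)

    def test_out_of_range_fraction_clamped_with_warning(self, fast_spec, caplog):
        cohort = CohortSpec(
            n_eyes=2, t1_spec=fast_spec, fd_percent_delta_per_ring=(-80.0,) * 5,
            split_factor=1.0, between_eye_sd=0.0, seed=1,
        )
        with caplog.at_level("WARNING"):
            records = generate_paired_cohort(cohort, render=False)
        assert "clamped" in caplog.text
        for rec in records:
            assert all(f == 0.0 for f in rec.t2[2].ring_truth_fractions)

    def test_cohort_spec_validation(self, fast_spec):
        with pytest.raises(ValueError):
            CohortSpec(n_eyes=1, t1_spec=fast_spec)
        with pytest.raises(ValueError):
            CohortSpec(n_eyes=5, t1_spec=fast_spec, split_factor=0.9)
        with pytest.raises(ValueError):
            CohortSpec(n_eyes=5, t1_spec=fast_spec, fd_percent_delta_per_ring=(0.0,) * 4)
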