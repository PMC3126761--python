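"""Phantom and isotherm generators: ground truth, determinism, degeneracy."""

import numpy as np
import pytest

from poremetry.errors import DegeneratePhantomError, InvalidParameterError
from poremetry.fixtures import (gap_widths_scanline, generate_bet_isotherm,
                                generate_cell_phantom, generate_disc_phantom,
                                generate_fibril_network, generate_slit_phantom,
                                render_tem, truth_gap_radii)


class TestSlitPhantom:
    @pytest.mark.parametrize("width_px, pitch, expected_gap", [
        (3, 2.34, 7.02), (1, 2.34, 2.34), (10, 1.0, 10.0)])
    def test_truth_gap_is_width_times_pitch(self, width_px, pitch, expected_gap):
        ph = generate_slit_phantom(width_px, pixel_pitch_nm=pitch)
        assert ph.truth_gaps == pytest.approx([expected_gap])
        # cavity is exactly width_px wide everywhere
        assert (~ph.truth_mask).sum(axis=1).tolist() == [width_px] * ph.shape[0]

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(InvalidParameterError):
            generate_slit_phantom(0)
        with pytest.raises(InvalidParameterError):
            generate_slit_phantom(3, wall_px=0)

    def test_scanline_oracle_agrees_with_kdtree_route(self):
        ph = generate_slit_phantom(7)
        runs = gap_widths_scanline(ph.truth_mask, ph.pixel_pitch_nm)
        radii, _ = truth_gap_radii(ph.truth_mask, ph.pixel_pitch_nm)
        # run width vs twice the medial nearest-wall distance: within one
        # pixel-center quantization step
        assert np.all(np.abs(runs - 2 * radii) <= ph.pixel_pitch_nm)


class TestDiscPhantom:
    def test_cavity_area_matches_disc(self):
        ph = generate_disc_phantom(8)
        assert (~ph.truth_mask).sum() == pytest.approx(np.pi * 64, rel=0.05)

    def test_smallest_disc_has_13_pixels(self):
        # enumeration: pixels with center distance <= 2 of the center
        assert (~generate_disc_phantom(2).truth_mask).sum() == 13

    def test_kdtree_max_radius_equals_disc_radius(self):
        ph = generate_disc_phantom(8)
        radii, _ = truth_gap_radii(ph.truth_mask, 1.0)
        assert radii.max() == pytest.approx(8, abs=0.5)

    def test_rejects_disc_exceeding_bounds(self):
        with pytest.raises(InvalidParameterError):
            generate_disc_phantom(8, image_px=(10, 10))
        with pytest.raises(InvalidParameterError):
            generate_disc_phantom(1)


class TestFibrilNetwork:
    def test_rejects_degenerate_count(self):
        with pytest.raises(InvalidParameterError):
            generate_fibril_network((64, 64), fibril_count=0)

    def test_same_seed_is_bit_identical(self):
        a = generate_fibril_network((128, 128), seed=7)
        b = generate_fibril_network((128, 128), seed=7)
        assert np.array_equal(a.truth_mask, b.truth_mask)
        assert np.array_equal(a.truth_gaps, b.truth_gaps)

    def test_density_reduces_cavity_fraction(self):
        lo, hi = [], []
        for seed in range(5):
            lo.append((~generate_fibril_network(
                (192, 192), fibril_count=15, seed=seed).truth_mask).mean())
            hi.append((~generate_fibril_network(
                (192, 192), fibril_count=30, seed=seed).truth_mask).mean())
        assert np.mean(hi) < np.mean(lo)

    def test_overdense_network_is_degenerate(self):
        with pytest.raises(DegeneratePhantomError):
            generate_fibril_network((48, 48), fibril_count=2000,
                                    fibril_width_px_dist=((9, 1.0),), seed=0)

    def test_truth_gaps_positive_with_multiplicities(self):
        ph = generate_fibril_network((256, 256), seed=3)
        assert (ph.truth_gaps > 0).all()
        assert ph.truth_gaps.size > 50  # one entry per medial point


class TestRenderTem:
    def test_zero_corruption_is_identity(self):
        ph = generate_slit_phantom(5)
        out = render_tem(ph, noise_sd=0, inhomogeneity_amplitude=0)
        assert np.array_equal(out.rendered, ph.rendered)

    def test_noise_only_render_is_unbiased(self):
        ph = generate_slit_phantom(5, length_px=32)
        acc = np.zeros(ph.shape)
        n = 100
        for seed in range(n):
            acc += render_tem(ph, noise_sd=8, inhomogeneity_amplitude=0,
                              seed=seed).rendered
        se = 8 / np.sqrt(n)
        assert np.abs(acc / n - ph.rendered).max() < 3 * se + 0.05

    def test_bias_field_creates_corner_gradient(self):
        ph = generate_fibril_network((256, 256), seed=5)
        out = render_tem(ph, noise_sd=0, inhomogeneity_amplitude=25,
                         inhomogeneity_scale_px=100, seed=9)

        def corner_diff(px):
            return abs(px[:64, :64].mean() - px[-64:, -64:].mean())

        assert corner_diff(out.rendered) > corner_diff(ph.rendered)

    def test_equal_contrast_rejected(self):
        with pytest.raises(InvalidParameterError):
            render_tem(generate_slit_phantom(3), contrast=(100, 100))


class TestCellPhantom:
    def test_cell_disc_area(self):
        ph = generate_cell_phantom(cell_radius_px=60, image_px=(256, 256),
                                   halo_small_pore_boost=0.0, seed=0)
        assert ph.cell_mask.sum() == pytest.approx(np.pi * 60 ** 2, rel=0.05)

    def test_boost_elevates_near_field_small_gaps(self):
        ph = generate_cell_phantom(halo_depth_nm=40, halo_small_pore_boost=0.3,
                                   image_px=(384, 384), cell_radius_px=60,
                                   seed=1)
        near = (ph.truth_gaps_near / 2 <= 10).mean()
        far = (ph.truth_gaps_far / 2 <= 10).mean()
        assert near > far

    def test_zero_boost_leaves_halo_density_unchanged(self):
        # with boost 0 no fibrils are added, so the alginate area fraction in
        # the halo ring matches the far field up to sampling noise. (The raw
        # near/far *gap* distributions differ even then: shallow-depth medial
        # points are geometrically censored toward small radii, a property of
        # interface-referenced porometry rather than of the generator.)
        from scipy import ndimage
        diffs = []
        for seed in range(10):
            ph = generate_cell_phantom(halo_small_pore_boost=0.0,
                                       image_px=(320, 320), cell_radius_px=50,
                                       seed=seed)
            depth = ndimage.distance_transform_edt(~ph.cell_mask) \
                * ph.pixel_pitch_nm
            ring = (depth > 0) & (depth <= ph.halo_depth_nm)
            far = depth > ph.halo_depth_nm
            diffs.append(ph.truth_mask[ring].mean()
                         - ph.truth_mask[far].mean())
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < max(3 * se, 0.02)

    def test_boost_densifies_halo_ring(self):
        from scipy import ndimage
        ph = generate_cell_phantom(halo_small_pore_boost=0.3,
                                   image_px=(320, 320), cell_radius_px=50,
                                   seed=2)
        depth = ndimage.distance_transform_edt(~ph.cell_mask) \
            * ph.pixel_pitch_nm
        ring = (depth > 0) & (depth <= ph.halo_depth_nm)
        far = depth > ph.halo_depth_nm
        assert ph.truth_mask[ring].mean() > ph.truth_mask[far].mean()

    def test_cell_larger_than_image_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_cell_phantom(cell_radius_px=200, image_px=(128, 128))
        with pytest.raises(InvalidParameterError):
            generate_cell_phantom(halo_depth_nm=500)


class TestBetIsothermGenerator:
    def test_amount_increasing_below_p03(self):
        iso = generate_bet_isotherm(245.0, p_grid=np.linspace(0.01, 0.29, 40))
        assert (np.diff(iso.adsorption[:, 1]) > 0).all()

    def test_noise_free_amounts_deterministic(self):
        a = generate_bet_isotherm(532.0, seed=1, noise_rel=0.01)
        b = generate_bet_isotherm(532.0, seed=1, noise_rel=0.01)
        assert np.array_equal(a.adsorption, b.adsorption)

    def test_invalid_pressure_grid_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_bet_isotherm(245.0, p_grid=[0.0, 0.1])
        with pytest.raises(InvalidParameterError):
            generate_bet_isotherm(245.0, C_bet=0.5)
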