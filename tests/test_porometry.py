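"""Core metrology: distance transform, skeletons, radii, binned distributions."""

import numpy as np
import pytest

from poremetry import (CalibratedImage, bin_distribution, bin_values,
                       compare_distributions, distance_transform,
                       extract_skeleton, measure_phase, measure_radii,
                       total_variation_distance)
from poremetry.errors import DegenerateMaskError, InvalidParameterError
from poremetry.fixtures import (generate_disc_phantom, generate_fibril_network,
                                generate_slit_phantom, render_tem)
from poremetry.porometry import BinnedDistribution, RPR_TABLE1_EDGES
from poremetry.report import measure_image
from poremetry.segment import PhaseMask, _label_cavities


def _phase_mask(mask, pitch=1.0):
    return PhaseMask(mask=np.asarray(mask, bool), pixel_pitch_nm=pitch,
                     labels=_label_cavities(np.asarray(mask, bool)))


def brute_force_edt(target):
    """O(n^2) oracle: per target pixel, min distance to any non-target pixel."""
    sources = np.argwhere(~target)
    out = np.zeros(target.shape)
    for r, c in np.argwhere(target):
        out[r, c] = np.sqrt(((sources - (r, c)) ** 2).sum(axis=1).min())
    return out


class TestDistanceTransform:
    def test_single_wall_pixel_geometry(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True  # lone alginate pixel
        dmap = distance_transform(_phase_mask(mask), "pore")
        assert dmap.values[0, 0] == pytest.approx(np.sqrt(8))
        assert dmap.values[2, 2] == 0.0

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(10):
            mask = rng.random((64, 64)) < 0.5
            if mask.all() or not mask.any():
                continue
            dmap = distance_transform(_phase_mask(mask), "pore")
            np.testing.assert_array_equal(dmap.values, brute_force_edt(~mask))

    def test_slit_width_3_values(self):
        ph = generate_slit_phantom(3, length_px=10, wall_px=3)
        dmap = distance_transform(_phase_mask(ph.truth_mask), "pore")
        row = dmap.values[5]
        assert row[3:6].tolist() == [1.0, 2.0, 1.0]

    def test_zero_exactly_on_walls_and_lipschitz(self, segmented_network):
        dmap = distance_transform(segmented_network, "pore")
        assert ((dmap.values == 0) == segmented_network.mask).all()
        assert np.abs(np.diff(dmap.values, axis=0)).max() <= np.sqrt(2) + 1e-9
        assert np.abs(np.diff(dmap.values, axis=1)).max() <= np.sqrt(2) + 1e-9

    def test_single_phase_mask_rejected(self):
        with pytest.raises(DegenerateMaskError):
            distance_transform(_phase_mask(np.ones((8, 8))), "pore")

    def test_fibril_mode_inverts_target(self, segmented_network):
        dmap = distance_transform(segmented_network, "fibril")
        assert ((dmap.values > 0) == segmented_network.mask).all()


class TestSkeleton:
    def test_odd_slit_skeleton_is_center_column(self):
        ph = generate_slit_phantom(5, length_px=20, wall_px=4)
        pm = _phase_mask(ph.truth_mask)
        dmap = distance_transform(pm, "pore")
        skel = extract_skeleton(dmap, pm)
        cols = set(np.argwhere(skel)[:, 1])
        assert cols == {4 + 2}  # wall + center offset

    def test_even_slit_tie_break_keeps_first_column(self):
        ph = generate_slit_phantom(4, length_px=20, wall_px=4)
        pm = _phase_mask(ph.truth_mask)
        skel = extract_skeleton(distance_transform(pm, "pore"), pm)
        cols = set(np.argwhere(skel)[:, 1])
        assert cols == {5}  # lexicographically first of the two center columns

    def test_disc_skeleton_degenerates_to_center_cluster(self):
        ph = generate_disc_phantom(8)
        pm = _phase_mask(ph.truth_mask)
        skel = extract_skeleton(distance_transform(pm, "pore"), pm)
        center = np.array(ph.shape) // 2
        assert skel.sum() <= 5
        assert skel[tuple(center)]

    def test_skeleton_strictly_thinner_than_phase(self, segmented_network):
        dmap = distance_transform(segmented_network, "pore")
        skel = extract_skeleton(dmap, segmented_network)
        assert 0 < skel.sum() < (~segmented_network.mask).sum()

    def test_every_lumen_has_a_skeleton_pixel(self, segmented_network):
        dmap = distance_transform(segmented_network, "pore")
        skel = extract_skeleton(dmap, segmented_network)
        labels = segmented_network.labels
        present = np.unique(labels[skel])
        assert set(range(1, labels.max() + 1)) <= set(present)


class TestMeasureRadii:
    def test_slit_modal_radius_half_gap(self):
        ph = generate_slit_phantom(10, pixel_pitch_nm=2.34)
        pm = _phase_mask(ph.truth_mask, 2.34)
        samples = measure_phase(pm, "pore")
        assert samples.modal_radius_px() == pytest.approx(5, abs=0.5)
        modal_nm = samples.modal_radius_px() * 2.34
        assert modal_nm == pytest.approx(11.7, abs=0.5 * 2.34)

    def test_disc_max_radius(self):
        ph = generate_disc_phantom(8)
        samples = measure_phase(_phase_mask(ph.truth_mask), "pore")
        assert samples.radii_px.max() == pytest.approx(8, abs=1)

    def test_frequency_table_counts_all_samples(self, segmented_network):
        samples = measure_phase(segmented_network, "pore")
        assert sum(samples.frequency_table.values()) == samples.n

    def test_empty_skeleton_warns(self, segmented_network):
        dmap = distance_transform(segmented_network, "pore")
        with pytest.warns(UserWarning):
            out = measure_radii(dmap, np.zeros(dmap.values.shape, bool))
        assert out.n == 0

    def test_skeleton_outside_phase_rejected(self, segmented_network):
        dmap = distance_transform(segmented_network, "pore")
        bad = segmented_network.mask.copy()  # alginate, not cavity
        with pytest.raises(InvalidParameterError):
            measure_radii(dmap, bad)

    @pytest.mark.parametrize("width", range(3, 16))
    def test_slit_recovery_through_full_pipeline(self, width, cfg):
        ph = render_tem(generate_slit_phantom(width, length_px=128), seed=width)
        samples = measure_image(
            CalibratedImage(ph.rendered, ph.pixel_pitch_nm), cfg)
        assert samples.modal_radius_px() == pytest.approx(
            np.ceil(width / 2), abs=0.5)


class TestBinning:
    def test_all_small_samples_land_in_first_class(self):
        d = bin_values(np.full(50, 5.0), "rpr_table1")
        assert d.percent.tolist() == [100, 0, 0, 0, 0, 0]

    def test_boundary_value_goes_to_lower_class(self):
        d = bin_values(np.array([10.0, 10.0001]), "rpr_table1")
        assert d.percent[0] == 50.0 and d.percent[1] == 50.0

    def test_uniform_samples_follow_bin_widths(self, rng):
        vals = rng.uniform(0, 80, 100_000)
        d = bin_values(vals, "rpr_table1")
        widths = np.array([10, 10, 5, 15, 30, 10])  # last: 70-80
        np.testing.assert_allclose(d.percent, 100 * widths / 80, atol=1.0)

    def test_percentages_sum_to_100(self, segmented_network):
        samples = measure_phase(segmented_network, "pore")
        d = bin_distribution(samples, "rpr_table1")
        assert d.percent.sum() == pytest.approx(100.0, abs=1e-9)
        assert d.n_samples == samples.n

    def test_flr_scheme_edges_are_pitch_multiples(self):
        d = bin_values(np.array([1.0, 3.0, 5.0, 8.0, 12.0]), "flr_table2")
        assert d.bin_edges_nm == (2.34, 4.68, 7.02, 9.36)
        assert d.percent.tolist() == [20, 20, 20, 20, 20]

    def test_empty_sample_set_rejected(self):
        with pytest.raises(InvalidParameterError):
            bin_values(np.array([]))


# Printed cross-validation columns for 0.8% and 1.4% w/v alginate:
# nitrogen-sorption vs image-analysis percent frequencies per rpr class.
CROSS_METHOD_COLUMNS = {
    "0.8_n2": (48.9, 15.4, 13.3, 11.3, 9.0, 2.2),
    "0.8_img": (49.4, 16.7, 11.1, 9.3, 11.0, 3.0),
    "1.4_n2": (59.8, 16.1, 8.9, 8.8, 5.3, 1.1),
    "1.4_img": (62.8, 19.9, 9.4, 4.7, 2.9, 1.0),
}


def published_distribution(key):
    return BinnedDistribution(RPR_TABLE1_EDGES, np.array(CROSS_METHOD_COLUMNS[key]), 0)


class TestCompareDistributions:
    def test_identical_distributions_are_zero(self):
        a = published_distribution("0.8_n2")
        cmp_ = compare_distributions(a, a)
        assert cmp_.max_abs_diff == 0.0
        assert (cmp_.per_bin_abs_diff == 0).all()

    def test_cross_method_agreement_08_alginate(self):
        cmp_ = compare_distributions(published_distribution("0.8_n2"),
                                     published_distribution("0.8_img"))
        # largest discrepancy sits in the 20-25 nm class; all below 5 points
        assert cmp_.max_abs_diff == pytest.approx(2.2, abs=1e-9)
        assert cmp_.argmax_bin == 2
        assert cmp_.max_abs_diff < 5.0

    def test_cross_method_agreement_14_alginate(self):
        cmp_ = compare_distributions(published_distribution("1.4_n2"),
                                     published_distribution("1.4_img"))
        assert cmp_.max_abs_diff == pytest.approx(4.1, abs=1e-9)
        assert cmp_.argmax_bin == 3  # the 25-40 nm class
        assert cmp_.max_abs_diff < 5.0

    def test_mismatched_edges_rejected(self):
        a = published_distribution("0.8_n2")
        b = bin_values(np.array([1.0, 3.0]), "flr_table2")
        with pytest.raises(InvalidParameterError):
            compare_distributions(a, b)


class TestDistributionRecovery:
    def test_network_phantom_tv_distance(self, network_phantom, cfg):
        samples = measure_image(
            CalibratedImage(network_phantom.rendered,
                            network_phantom.pixel_pitch_nm), cfg)
        measured = bin_values(samples.radii_nm, "rpr_table1")
        truth = bin_values(network_phantom.truth_rpr_nm, "rpr_table1")
        assert total_variation_distance(measured, truth) <= 0.15

    def test_fibril_width_mode_recovered(self, network_phantom,
                                         segmented_network):
        samples = measure_phase(segmented_network, "fibril")
        measured_mode_px = samples.modal_radius_px()
        widths_px = network_phantom.truth_fibril_widths / \
            network_phantom.pixel_pitch_nm
        vals, counts = np.unique(np.round(widths_px).astype(int),
                                 return_counts=True)
        modal_width = vals[np.argmax(counts)]
        # a width-w band has center-axis EDT about (w+1)/2 px
        assert abs(measured_mode_px - (modal_width + 1) / 2) <= 1.0
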