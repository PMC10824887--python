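"""Puncta detection and measurement: both modes, the volume filter, and
cross-mode matching."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from endopuncta import puncta
from endopuncta.geometry import add_sphere_occupancy
from endopuncta.puncta import (
    PunctaFilter,
    SpotsParams,
    SurfaceParams,
    apply_filter,
    detect_spots_mode,
    detect_surface_mode,
    diameter_from_volume,
    match_modes,
    sphere_volume_from_diameter,
)
from endopuncta.stack_io import VoxelSpacing

SPACING = VoxelSpacing(0.03, 0.03, 0.13)
PSF = (0.08, 0.08, 0.15)
SIG_VOX = (PSF[2] / SPACING.dz, PSF[1] / SPACING.dy, PSF[0] / SPACING.dx)


def render(centers_um, diameters_um, shape=(14, 160, 160), amplitude=1000.0):
    vol = np.zeros(shape)
    for c, d in zip(centers_um, diameters_um):
        add_sphere_occupancy(vol, SPACING, c, d / 2.0, amplitude)
    return ndimage.gaussian_filter(vol, SIG_VOX, mode="constant")


class TestSphereGeometry:
    @pytest.mark.parametrize(
        "d,expected", [(0.2, 0.00419), (0.0, 0.0), (0.5, 0.06545)]
    )
    def test_volume_from_diameter(self, d, expected):
        assert sphere_volume_from_diameter(d) == pytest.approx(expected, abs=5e-5)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            sphere_volume_from_diameter(-0.1)

    @given(st.floats(min_value=1e-6, max_value=10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_diameter_volume_round_trip(self, v):
        assert sphere_volume_from_diameter(float(diameter_from_volume(v))) == pytest.approx(
            v, rel=1e-9
        )


class TestFilter:
    def test_strict_less_than_exclusion_at_lower_bound(self):
        """The published exclusion is strict (<0.004 μm³), so a volume of
        exactly 0.004 is retained."""
        table = pd.DataFrame({"volume_um3": [0.003, 0.004, 0.005]})
        out = apply_filter(table, PunctaFilter(min_volume_um3=0.004, max_volume_um3=np.inf))
        assert out["volume_um3"].tolist() == [0.004, 0.005]

    def test_default_bounds_are_protocol_constants(self):
        filt = PunctaFilter()
        assert filt.min_volume_um3 == 0.004
        assert filt.max_volume_um3 == pytest.approx(sphere_volume_from_diameter(0.5))

    def test_empty_table_passes_through(self):
        out = apply_filter(pd.DataFrame({"volume_um3": []}), PunctaFilter())
        assert len(out) == 0

    def test_identity_with_open_bounds(self):
        table = pd.DataFrame({"volume_um3": [0.001, 0.01, 0.2]})
        out = apply_filter(table, PunctaFilter(min_volume_um3=0.0, max_volume_um3=np.inf))
        assert out["volume_um3"].tolist() == table["volume_um3"].tolist()

    @given(st.lists(st.floats(min_value=1e-4, max_value=0.1), min_size=0, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_idempotent(self, volumes):
        table = pd.DataFrame({"volume_um3": volumes})
        counts = []
        for lo in (0.001, 0.004, 0.01):
            filt = PunctaFilter(min_volume_um3=lo, max_volume_um3=np.inf)
            out = apply_filter(table, filt)
            counts.append(len(out))
            assert apply_filter(out, filt).equals(out.reset_index(drop=True))
        assert counts == sorted(counts, reverse=True)


class TestSurfaceMode:
    def test_well_separated_puncta_recovered_exactly(self):
        """20 well-separated 400 nm puncta: every object found, each
        volume within ±35% of truth."""
        rng = np.random.default_rng(0)
        centers = []
        while len(centers) < 20:
            c = (rng.uniform(0.5, 4.3), rng.uniform(0.5, 4.3), rng.uniform(0.5, 1.3))
            if all(np.linalg.norm(np.subtract(c, o)) >= 0.7 for o in centers):
                centers.append(c)
        img = render(centers, [0.4] * 20)
        table = detect_surface_mode(img, SPACING, SurfaceParams())
        assert len(table) == 20
        truth_v = sphere_volume_from_diameter(0.4)
        assert np.all(np.abs(table["volume_um3"] / truth_v - 1) <= 0.35)
        pairs = puncta.match_to_truth(
            table[["cx_um", "cy_um", "cz_um"]].to_numpy(), np.asarray(centers), 0.15
        )
        assert len(pairs) == 20

    def test_close_pair_split_by_watershed(self):
        img = render([(1.75, 1.9, 0.91), (2.25, 1.9, 0.91)], [0.3, 0.3])
        table = detect_surface_mode(img, SPACING, SurfaceParams())
        assert len(table) == 2

    def test_all_zero_channel_yields_empty_table(self):
        table = detect_surface_mode(np.zeros((14, 64, 64)), SPACING, SurfaceParams())
        assert len(table) == 0
        assert list(table.columns) == puncta.SURFACE_COLUMNS

    def test_equivalent_diameter_consistent_with_volume(self):
        img = render([(1.9, 1.9, 0.91)], [0.35])
        table = detect_surface_mode(img, SPACING, SurfaceParams())
        v, d = table["volume_um3"].iloc[0], table["equivalent_diameter_um"].iloc[0]
        assert sphere_volume_from_diameter(d) == pytest.approx(v, rel=1e-9)

    def test_sphericity_near_one_for_spheres(self):
        img = render([(1.9, 1.9, 0.91)], [0.45])
        table = detect_surface_mode(img, SPACING, SurfaceParams())
        assert 0.5 < table["sphericity"].iloc[0] <= 1.0

    def test_occupancy_volume_reported_alongside_model(self):
        img = render([(1.9, 1.9, 0.91)], [0.4])
        table = detect_surface_mode(img, SPACING, SurfaceParams())
        assert table["volume_occupancy_um3"].iloc[0] > 0

    def test_without_psf_falls_back_to_occupancy(self):
        img = render([(1.9, 1.9, 0.91)], [0.4])
        table = detect_surface_mode(img, SPACING, SurfaceParams(psf_sigma_um=None))
        assert table["volume_um3"].iloc[0] == table["volume_occupancy_um3"].iloc[0]


class TestSpotsMode:
    def test_isolated_punctum_scale_estimate(self):
        """A single 300 nm punctum yields one spot with an estimated
        diameter in [0.2, 0.45] μm."""
        img = render([(1.9, 1.9, 0.91)], [0.3])
        spots = detect_spots_mode(img, SPACING, (0.1, 0.5), SpotsParams())
        assert len(spots) == 1
        assert 0.2 <= spots["scale_um"].iloc[0] <= 0.45

    def test_uniform_background_gives_no_spots(self):
        spots = detect_spots_mode(np.full((14, 64, 64), 5.0), SPACING, (0.1, 0.5))
        assert len(spots) == 0

    def test_centers_accurate_to_150nm(self):
        centers = [(1.2, 1.2, 0.7), (3.0, 1.5, 1.1), (2.0, 3.4, 0.9)]
        img = render(centers, [0.25, 0.35, 0.45])
        spots = detect_spots_mode(img, SPACING, (0.1, 0.5), SpotsParams())
        pairs = puncta.match_to_truth(
            spots[["cx_um", "cy_um", "cz_um"]].to_numpy(), np.asarray(centers), 0.15
        )
        assert len(pairs) == len(centers)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            detect_spots_mode(np.ones((5, 8, 8)), SPACING, (0.5, 0.5))


class TestMatchModes:
    def test_identical_clean_input_matches_both_ways(self):
        centers = [(1.2, 1.2, 0.7), (3.0, 1.5, 1.1), (2.0, 3.4, 0.9), (3.8, 3.6, 0.6)]
        img = render(centers, [0.3] * 4)
        surface = detect_surface_mode(img, SPACING, SurfaceParams())
        spots = detect_spots_mode(img, SPACING, (0.1, 0.5), SpotsParams())
        report = match_modes(surface, spots, tolerance_um=0.3)
        assert report.frac_surface_matched >= 0.9
        assert report.frac_spots_matched >= 0.9

    def test_empty_spots_gives_zero_fraction(self):
        surface = pd.DataFrame({"id": [1], "cx_um": [1.0], "cy_um": [1.0], "cz_um": [0.5]})
        report = match_modes(surface, pd.DataFrame(columns=puncta.SPOT_COLUMNS), 0.3)
        assert report.n_matched == 0
        assert report.frac_surface_matched == 0.0

    def test_zero_tolerance_matches_only_coincident(self):
        a = pd.DataFrame({"id": [1, 2], "cx_um": [1.0, 2.0], "cy_um": [1.0, 2.0], "cz_um": [0.5, 0.5]})
        b = pd.DataFrame({"id": [1, 2], "cx_um": [1.0, 2.1], "cy_um": [1.0, 2.0], "cz_um": [0.5, 0.5]})
        report = match_modes(a, b, tolerance_um=0.0)
        assert report.pairs == [(1, 1)]


def test_surface_total_volume_bounded_by_roi(clean_phantom, clean_rois):
    from endopuncta.roi import mask_channel

    stack, _ = clean_phantom
    somato, _, _ = clean_rois
    masked = mask_channel(stack, somato)
    table = detect_surface_mode(masked, stack.spacing, SurfaceParams(), roi=somato)
    assert table["volume_um3"].sum() <= somato.volume_um3
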