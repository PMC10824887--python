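"""ROI construction: segmentation fidelity, deterministic refinement,
masking contracts and QC."""

import numpy as np
import pytest
from scipy import ndimage

from endopuncta.roi import (
    QCConfig,
    RoiMask,
    RoiSelectionError,
    SegmentationError,
    SegmentationParams,
    mask_channel,
    qc_neuron,
    refine_perinuclear,
    refine_somatodendritic,
    segment_nuclei,
    segment_somatodendritic,
)
from endopuncta.stack_io import ChannelRoleMap, ImageStack, VoxelSpacing

SPACING = VoxelSpacing(0.03, 0.03, 0.13)


def _jaccard(a, b):
    return np.logical_and(a, b).sum() / np.logical_or(a, b).sum()


class TestSegmentation:
    def test_somatodendritic_mask_matches_truth(self, clean_phantom, clean_rois):
        stack, truth = clean_phantom
        raw = segment_somatodendritic(stack, SegmentationParams())
        signal = truth.masks["somatodendritic_region"] | truth.masks["neurite_fragments"]
        assert _jaccard(raw.voxels, signal) >= 0.8
        somato, _, _ = clean_rois
        assert _jaccard(somato.voxels, truth.masks["somatodendritic_region"]) >= 0.8
        # refined mask covers ≥95% of the true signal region
        assert (
            np.logical_and(somato.voxels, truth.masks["somatodendritic_region"]).sum()
            >= 0.95 * truth.masks["somatodendritic_region"].sum()
        )

    def test_raw_mask_has_fragment_components(self, clean_phantom, clean_spec):
        """Soma+dendrite plus each disconnected neurite fragment appear as
        separate components before refinement."""
        stack, _ = clean_phantom
        raw = segment_somatodendritic(stack, SegmentationParams())
        assert raw.labels.max() == 1 + clean_spec.n_disconnected_neurites

    def test_nuclei_components_match_truth(self, clean_phantom, clean_spec, clean_rois):
        _, _, nuclei = clean_rois
        assert nuclei.max() == 1 + clean_spec.n_distractor_nuclei

    def test_blank_channel_raises(self):
        stack = ImageStack(
            intensities=np.zeros((3, 5, 32, 32), dtype=np.float32),
            spacing=SPACING,
            roles=ChannelRoleMap(0, 1, 2),
        )
        with pytest.raises(SegmentationError, match="MAP2"):
            segment_somatodendritic(stack, SegmentationParams())
        with pytest.raises(SegmentationError):
            segment_nuclei(stack, SegmentationParams())

    def test_abutting_nuclei_split_by_watershed(self):
        """Two overlapping spherical nuclei are separated into two labels."""
        shape = (14, 160, 160)
        ch = np.zeros(shape)
        zz, yy, xx = np.mgrid[:14, :160, :160].astype(float)
        zu, yu, xu = (zz + 0.5) * 0.13, (yy + 0.5) * 0.03, (xx + 0.5) * 0.03
        for cx in (1.6, 3.2):
            ch[((xu - cx) ** 2 + (yu - 2.4) ** 2) / 0.81 + ((zu - 0.91) / 0.45) ** 2 <= 1] = 800.0
        ch = ndimage.gaussian_filter(ch, (1.0, 2.0, 2.0))
        stack = ImageStack(
            intensities=np.stack([ch, ch, ch]).astype(np.float32),
            spacing=SPACING,
            roles=ChannelRoleMap(0, 1, 2),
        )
        labels = segment_nuclei(stack, SegmentationParams())
        assert labels.max() == 2


class TestRefinement:
    def test_only_nucleus_bearing_component_kept(self, clean_phantom, clean_rois):
        _, truth = clean_phantom
        somato, _, _ = clean_rois
        assert somato.n_components == 1
        # fragments are gone: no overlap with any truth fragment
        assert not (somato.voxels & truth.masks["neurite_fragments"]).any()

    def test_refine_is_idempotent(self, clean_phantom, clean_rois):
        stack, _ = clean_phantom
        somato, _, nuclei = clean_rois
        again = refine_somatodendritic(
            RoiMask(voxels=somato.voxels, role="somatodendritic", spacing=stack.spacing),
            nuclei > 0,
        )
        np.testing.assert_array_equal(again.voxels, somato.voxels)

    def test_single_component_is_identity(self, clean_phantom, clean_rois):
        stack, _ = clean_phantom
        somato, _, nuclei = clean_rois
        out = refine_somatodendritic(somato, nuclei > 0)
        np.testing.assert_array_equal(out.voxels, somato.voxels)

    def test_no_overlap_raises_selection_error(self, clean_phantom, clean_rois):
        stack, _ = clean_phantom
        somato, _, _ = clean_rois
        far_seed = np.zeros_like(somato.voxels)
        far_seed[0, 0, 0] = True
        with pytest.raises(RoiSelectionError, match="nucleus"):
            refine_somatodendritic(
                RoiMask(voxels=somato.voxels, role="somatodendritic", spacing=SPACING),
                far_seed,
            )

    def test_perinuclear_selects_neuronal_nucleus(self, clean_phantom, clean_rois):
        _, truth = clean_phantom
        _, perinuc, _ = clean_rois
        nucleus = perinuc.seed_voxels
        assert _jaccard(nucleus, truth.masks["nucleus"]) >= 0.7
        assert not (nucleus & truth.masks["distractor_nuclei"]).any()

    def test_zero_dilation_reproduces_nucleus(self, clean_rois):
        somato, _, nuclei = clean_rois
        bare = refine_perinuclear(nuclei, somato, dilation_um=0.0)
        np.testing.assert_array_equal(bare.voxels, bare.seed_voxels)

    def test_dilation_strictly_grows_volume(self, clean_rois):
        somato, _, nuclei = clean_rois
        bare = refine_perinuclear(nuclei, somato, dilation_um=0.0)
        grown = refine_perinuclear(nuclei, somato, dilation_um=0.3)
        assert grown.volume_um3 > bare.volume_um3


class TestMaskChannel:
    def test_full_roi_is_identity(self, clean_phantom):
        stack, _ = clean_phantom
        full = RoiMask(
            voxels=np.ones(stack.grid_shape, dtype=bool),
            role="somatodendritic",
            spacing=stack.spacing,
        )
        np.testing.assert_array_equal(mask_channel(stack, full), stack.channel("puncta"))

    def test_empty_roi_zeroes_channel(self, clean_phantom):
        stack, _ = clean_phantom
        empty = RoiMask(
            voxels=np.zeros(stack.grid_shape, dtype=bool),
            role="somatodendritic",
            spacing=stack.spacing,
        )
        assert mask_channel(stack, empty).sum() == 0

    def test_never_increases_and_zero_outside(self, clean_phantom, clean_rois):
        stack, _ = clean_phantom
        somato, _, _ = clean_rois
        masked = mask_channel(stack, somato)
        ch = stack.channel("puncta")
        assert masked.sum() <= ch.sum()
        assert masked[~somato.voxels].sum() == 0
        np.testing.assert_array_equal(masked[somato.voxels], ch[somato.voxels])

    def test_somatodendritic_mask_keeps_interior_puncta_flux(self, clean_phantom, clean_rois):
        """Somatodendritic puncta are placed interior to the MAP2 region,
        so the masked channel retains ≥99% of total somatodendritic flux."""
        stack, truth = clean_phantom
        somato, _, _ = clean_rois
        masked = mask_channel(stack, somato)
        # perinuclear puncta and granule bleed live well outside this ROI:
        # flux inside a slightly grown ROI is almost entirely somatodendritic
        grown = ndimage.binary_dilation(somato.voxels, iterations=3)
        ch = stack.channel("puncta")
        assert masked.sum() / ch[grown].sum() >= 0.97

    def test_grid_mismatch_raises(self, clean_phantom):
        stack, _ = clean_phantom
        bad = RoiMask(voxels=np.ones((2, 2, 2), dtype=bool), role="perinuclear", spacing=SPACING)
        with pytest.raises(ValueError, match="grid"):
            mask_channel(stack, bad)


class TestVolumesAndQC:
    def test_volume_is_exact_voxel_count_times_voxel_volume(self, clean_rois):
        somato, perinuc, _ = clean_rois
        for m in (somato, perinuc):
            assert m.volume_um3 == m.voxels.sum() * m.spacing.voxel_volume_um3

    def test_intact_neuron_passes(self, clean_rois):
        somato, perinuc, _ = clean_rois
        report = qc_neuron(somato, perinuc)
        assert report.passed and not report.reasons

    def test_fragmented_map2_fails_as_discontinuous(self, clean_rois):
        somato, perinuc, _ = clean_rois
        cracked = somato.voxels.copy()
        cracked[:, :, 100:104] = False  # simulated tissue cracking
        report = qc_neuron(
            RoiMask(voxels=cracked, role="somatodendritic", spacing=somato.spacing),
            perinuc,
        )
        assert not report.passed
        assert any("discontinuous" in r for r in report.reasons)

    def test_volume_bound_violation_reports_reason(self, clean_rois):
        somato, perinuc, _ = clean_rois
        report = qc_neuron(somato, perinuc, QCConfig(min_somatodendritic_volume_um3=1e4))
        assert not report.passed
        assert any("volume" in r for r in report.reasons)

    def test_missing_roi_never_throws(self):
        report = qc_neuron(None, None)
        assert not report.passed
        assert len(report.reasons) == 2
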