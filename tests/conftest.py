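"""Shared fixtures: session-scoped phantoms and their segmented ROIs.

Phantom rendering plus ROI construction costs a couple of seconds per
image, so tests that only inspect results share one clean and one noisy
phantom instead of regenerating them.
"""

from dataclasses import replace

import numpy as np
import pytest

from endopuncta import phantom, roi


@pytest.fixture(scope="session")
def clean_spec():
    return replace(phantom.default_spec(seed=1), noise=phantom.NoiseSpec(enabled=False))


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return phantom.generate_phantom(clean_spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    return phantom.generate_phantom(phantom.default_spec(seed=2))


@pytest.fixture(scope="session")
def clean_rois(clean_phantom):
    """(somatodendritic RoiMask, perinuclear RoiMask, nuclei labels) of the clean phantom."""
    stack, _ = clean_phantom
    params = roi.SegmentationParams()
    nuclei = roi.segment_nuclei(stack, params)
    raw = roi.segment_somatodendritic(stack, params)
    somato = roi.refine_somatodendritic(raw, nuclei > 0)
    perinuc = roi.refine_perinuclear(nuclei, somato, dilation_um=0.3)
    return somato, perinuc, nuclei


def truth_in_roi(truth, roi_mask, spacing):
    """Rows of the truth table whose centers fall inside the ROI mask."""
    nz, ny, nx = roi_mask.voxels.shape
    inside = [
        roi_mask.voxels[
            min(int(z / spacing.dz), nz - 1),
            min(int(y / spacing.dy), ny - 1),
            min(int(x / spacing.dx), nx - 1),
        ]
        for x, y, z in truth.puncta[["cx_um", "cy_um", "cz_um"]].to_numpy()
    ]
    return truth.puncta[np.asarray(inside, dtype=bool)]
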