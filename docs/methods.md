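# Methods

`endopuncta` quantifies the morphology and spatial clustering of
endosome-scale fluorescent puncta (EEA1, SORLA, or any punctate marker)
inside two neuronal regions of interest segmented from high-resolution
confocal z-stacks: a **somatodendritic** ROI from a MAP2-like
cytoskeletal channel and a **perinuclear** ROI from the nuclear (DAPI)
channel. This note documents the models, the defaults and why they were
chosen, the synthetic phantom used for validation, and the known
limitations.

## Coordinate and data conventions

Stacks are `(channel, z, y, x)` arrays with physical voxel spacing
`(dx, dy, dz)` in μm; anisotropy (dz ≫ dx) is the norm. Voxel *centers*
sit at `(index + 0.5) × spacing`, and every exported centroid, distance
and volume is in physical μm / μm³. ROI masks are binary volumes
serialized as 8-bit TIFF (0/255) that round-trip bit-exactly, which is
what makes the hand-edit step between the two batch stages possible.

## Acquisition profile and sampling QC

The default acquisition profile mirrors a high-resolution confocal
protocol: 0.03 × 0.03 μm lateral pixels, 0.13 μm z-steps, 14 planes
(1.82 μm total depth). `check_nyquist` verifies the ≥2× lateral
oversampling guideline using a configurable optics-limited lateral
resolution; the default of 0.2 μm is a diffraction-scale figure for
1.4 NA green emission and is this package's own choice — it affects only
the QC verdict, never a measurement.

## Deconvolution stage

Commercial acquisition software typically applies a proprietary adaptive
deconvolution. The pipeline instead offers a classical Richardson–Lucy
stage with a separable Gaussian PSF (`deconvolve.enabled`, default
**off**): 20 iterations by default, reflective edge handling,
non-negativity preserved at every step, flux conserved to ~1% in the
interior. It is an explicit, documented stand-in, not a reproduction of
any vendor algorithm; because the surface-mode measurement models the
PSF directly (below), the default pipeline bypasses deconvolution, and
pre-deconvolved input is equally acceptable — all downstream stages are
indifferent to whether the stage ran.

## ROI construction

Both channels are segmented the same way: anisotropic Gaussian
smoothing (σ = (0.06, 0.06, 0.13) μm), a global Otsu threshold
(parameter-free; percentile and absolute thresholds are available),
morphological closing (0.09 μm), and removal of components below
0.05 μm³. The published workflow's manual steps are replaced by
deterministic selection rules:

* *somatodendritic*: of the thresholded MAP2 components, keep exactly
  the one whose slice-filled extent contains the nucleus (manual
  analogue: deleting surfaces over disconnected distal neurites). Slice
  filling matters because MAP2 signal is absent from the nucleus and the
  organelle-dense perinuclear zone, so the component is an annulus in
  mid-stack planes.
* *perinuclear*: nuclei are split by a distance-transform watershed
  whose markers are h-maxima of the EDT (h = 0.1 μm) — a pinch between
  touching nuclei must be at least that deep before a cut is made, which
  keeps a single (possibly invaginated) nucleus intact. The nucleus with
  maximal overlap with the somatodendritic ROI is kept (manual analogue:
  deleting non-neuronal nuclei) and dilated isotropically by 0.3 μm.
  The dilation operationalizes the observation that perinuclear puncta
  surround, but do not colocalize with, the DNA stain; 0 reproduces the
  bare nuclear surface.

Ties in either selection are broken by overlap, then component volume,
then label order — documented and deterministic. A QC report
(never-throwing) checks single-component MAP2 connectivity, an intact
single nucleus, ROI volume bounds, and nucleus-inside-neuron
containment; failing images are excluded from analysis exactly as
neurons with discontinuous staining are excluded at selection time.

## Puncta detection

Both modes operate on the ROI-masked puncta channel.

**Surface mode** (explicit segmentation): a separable box-opening
top-hat (0.5 μm) removes smooth background; the image is smoothed at
near-matched-filter scale (σ = (0.05, 0.05, 0.1) μm); the detection
threshold is `median + 5 × (P84 − median)` over ROI voxels (the
upper-percentile scale replaces the MAD, which collapses on zero-clipped
photon-count backgrounds), floored at 2% of the image maximum for
noise-free data. Objects are grown on a lower support threshold, split
by a watershed seeded at local maxima ≥0.2 μm apart, and regions whose
peak rises above a shared saddle by less than half its height *and*
whose peaks are within 0.45 μm are re-merged — noise on a bright punctum
makes spurious shallow maxima on its own tails, whereas a genuine
z-neighbour (shallow dip because of axial blur) sits further away.
Single-voxel spikes are rejected by a 4-voxel minimum core.

**Volume estimation.** A 100–500 nm vesicle is at or below the optical
resolution, so any thresholded voxel count measures mostly the PSF. Two
estimates are therefore reported per object:

* `volume_occupancy_um3`: 3× supersampled occupancy above the object's
  half-maximum — the conventional segmentation volume, PSF-floor-limited
  at small sizes;
* `volume_um3` (primary when the PSF is configured): the object is
  modeled as a uniform sphere — the same spherical assumption used to
  derive the minimum-volume threshold from EM diameters — blurred by the
  known Gaussian PSF, and the model is least-squares fitted to the local
  image patch over center, radius, amplitude and background. The
  closed-form peak-to-flux ratio of a blurred sphere (strictly
  decreasing in radius) provides the initial radius. Voxels zeroed by
  ROI masking or claimed by neighbouring objects are excluded from the
  fit, so boundary truncation does not shrink volumes. For
  photon-counting data clipped at zero, the fit adds the analytic
  clipped-mean excess `E[max(N(λ, λ+σ_r²), 0)] − λ` to its prediction
  (σ_r = `read_noise_sd`, default 2 intensity units, 0 disables):
  without it the near-zero background sits ~σ_r·φ(0) above the model
  and volumes are biased several percent low. On noise-free phantoms the
  estimator is exact to ~1% for diameters ≥200 nm; below ~150 nm the
  amplitude–size degeneracy limits identifiability and estimates become
  noisy (such objects fall below the 0.004 μm³ filter anyway).

The **volume filter** retains `min ≤ v ≤ max` with the published strict
`< 0.004 μm³` exclusion semantics: a volume exactly at the threshold is
kept. The upper bound (the 500 nm sphere, ≈0.0654 μm³) is an extension
motivated by the same EM size range — the published protocol states only
the lower cut — and can be disabled (`max = inf`) for exact protocol
parity; it exists to reject fused autofluorescent blobs.

**Spots mode** (point detection): multiscale Laplacian of Gaussian with
anisotropy-corrected scales. For a sphere of diameter d the per-axis
detection σ is `sqrt((d/(2√3))² + σ_PSF²)` converted to voxels of that
axis; seven scales span the 100–500 nm range. Centers are refined by a
local intensity center of mass; the estimated diameter subtracts the PSF
variance again and is clamped into the configured range.

`match_modes` cross-validates the two workflows by greedy one-to-one
nearest-center matching under a tolerance (default 0.3 μm), reporting
the matched fraction in both directions.

## Morphology and clustering statistics

Per punctum: intensity-weighted centroid, volume, equivalent spherical
diameter, sphericity (marching-cubes surface of the supersampled
occupancy), intensities, and the mean Euclidean distance to the k = 3
nearest neighbouring puncta (exact KD-tree; NaN when the ROI holds fewer
than k+1 puncta). Neighbours are computed within a single ROI of a
single image only; centroid-to-centroid distance is used (surface-to-
surface is a plausible alternative the upstream tooling leaves
unspecified). A punctum belongs to an ROI iff its centroid lies inside
the ROI mask; the two ROIs are analyzed independently and may overlap.

Per image: count, volume distribution summary (mean, sd, median, Q1/Q3
by linear interpolation between order statistics, min, max), density =
count / ROI volume (the product reproduces the count to 1e-9
relative — tested on every output row), and mean 3-NN distance. Per
case: unweighted mean and sd across that case's images, every imaged
neuron contributing equally regardless of its puncta count.

## The synthetic phantom

The phantom is the package's study condition, not a tuning knob. The
default renders a 256 × 256 × 14 stack at (0.03, 0.03, 0.13) μm — a
7.68 × 7.68 × 1.82 μm field, a desk-scale crop of the full-frame
protocol — containing:

* one soma (ellipsoid, semi-axes 2.6 × 2.2 × 0.68 μm) with a tapering
  dendrite, rendered in the MAP2-like channel *minus* a perinuclear
  exclusion zone (nucleus ⊕ 0.55 μm): MAP2 binds dendritic/peripheral
  microtubule bundles and is sparse in the organelle-dense perinuclear
  region, and the exclusion keeps the two analysis compartments
  spatially unambiguous;
* one neuronal nucleus (semi-axes 0.95 × 0.8 × 0.42 μm) with a
  low-order azimuthal-harmonic radial perturbation (amplitude 0.08)
  giving the invaginated, non-convex contour real neuronal nuclei show,
  plus 2 distractor nuclei and 3 disconnected neurite fragments that the
  refinement rules must remove;
* 12 somatodendritic + 6 perinuclear puncta with a 0.6 μm minimum
  separation (the largest hard-core packing the small field supports
  comfortably), volumes drawn from a log-normal law μ_log = ln(0.008),
  σ_log = 0.45 truncated to 100–500 nm diameters — right-skewed with
  mean diameter ≈250 nm, matching the qualitative "flame-shaped,
  skewed toward smaller volumes" description of endosome distributions.
  Somatodendritic puncta are placed ≥0.25 μm interior to the MAP2 region
  and ≥(r + 0.1 μm) from the stack's z-faces so the masked channel keeps
  essentially all their blurred flux; perinuclear puncta occupy the
  0.05–0.25 μm band of the shell outside the nucleus, never overlapping
  it. Optional Thomas-process clustering is available;
* 3 lipofuscin-like autofluorescent granules (0.25–0.4 μm radius)
  bleeding into all three channels at 0.3 of their amplitude, placed
  outside both analysis ROIs — they model residual neuropil
  autofluorescence after quenching, whose level the literature describes
  only as "low"; an in-ROI granule stress case remains configurable;
* spheres rasterized by 3× supersampled analytic voxel overlap (naive
  binary rasterization quantizes 100–200 nm spheres to zero volume in a
  0.13 μm z grid), Gaussian PSF blur (σ = (0.08, 0.08, 0.15) μm, a
  1.4 NA confocal scale), and optionally Poisson shot noise at a photon
  scale giving peak SNR ≈ 10 plus Gaussian read noise (σ = 2), clipped
  at zero.

All randomness flows from one seeded `numpy` PCG64 generator; identical
spec + seed reproduce the stack bit-for-bit.

**What the phantom does not emulate** — and hence what passing tests do
not establish about real tissue: spatially varying staining efficiency
and amplitude variation between vesicles (rendered amplitude is
constant, which is what lets the spherical fit recover volumes so
accurately); non-Gaussian PSF structure, spherical aberration and
depth-dependent blur; tissue autofluorescence textures beyond discrete
granules; true vesicle shape deviations from sphericity; chromatic
misregistration. Count-recovery and law-recovery results on phantoms are
upper bounds on real-data performance.

## Pipeline structure and determinism

The two-batch structure is preserved deliberately: batch 1 writes
editable ROI masks and a QC table; batch 2 reloads masks (hand-edited or
not), analyzes both masked channels with both workflows, and aggregates
image and case summaries. `pause_for_edit` stops between the two. Per-
image failures (unreadable file, empty segmentation, QC exclusion) are
recorded in the run manifest and never abort the batch or perturb other
images. No stage after phantom generation consumes randomness, so two
runs over the same inputs produce byte-identical CSVs; the manifest
echoes the full configuration for provenance.

## Problem sizes used in tests and the acceptance script

The validation study uses 20 noise-free + 20 noisy phantoms for count
and spot-position recovery, 100 random point sets (n ≤ 200) for the
exact brute-force kNN cross-check, a 3-case × 8-image cohort for
case-level volume-law recovery, and a 2-image cohort run twice for the
byte-identity check — sizes chosen so the whole study runs in minutes on
a single CPU while keeping the statistical criteria meaningful.

## Known limitations

* Volumes below ~0.002 μm³ (d ≲ 160 nm) are at the identifiability
  floor of the spherical fit; they are excluded by the default filter
  but appear in unfiltered tables with inflated variance.
* The perinuclear ROI is a thin shell; puncta near its outer boundary
  lose part of their blurred flux to masking, and although the fit
  excludes masked voxels rather than counting them as zeros, perinuclear
  volume statistics remain noisier than somatodendritic ones.
* Otsu thresholding assumes a clear foreground/background bimodality
  per channel; dim or fragmented staining should use the percentile or
  absolute threshold options plus the QC report.
* One neuron per field is assumed (as in the acquisition protocol);
  multi-neuron instance segmentation is out of scope.
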