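"""Seeded synthetic confocal phantoms with known ground truth.

Generates 3-channel (nuclear / somatodendritic / puncta) z-stacks that
emulate a high-resolution confocal acquisition of a single cortical
neuron: one MAP2-like soma with a tapering dendrite, one nucleus with
invaginated contours plus distractor nuclei, disconnected neurite
fragments, sub-resolution endosome-like puncta with a right-skewed
volume law, lipofuscin-like autofluorescent granules, Gaussian PSF blur
and Poisson/read noise.

All randomness flows from a single ``numpy.random.Generator`` seeded by
``PhantomSpec.seed``; identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .geometry import add_sphere_occupancy
from .stack_io import AcquisitionProfile, ChannelRoleMap, ImageStack, VoxelSpacing, write_stack


class PlacementError(RuntimeError):
    """A punctum or structure could not be placed under the constraints."""


# ---------------------------------------------------------------------------
# Spec dataclasses


@dataclass(frozen=True)
class EllipsoidSpec:
    center_um: Tuple[float, float, float]  # (x, y, z)
    semi_axes_um: Tuple[float, float, float]  # (sx, sy, sz)


@dataclass(frozen=True)
class DendriteSpec:
    """Tapering cylinder leaving the soma surface.

    ``direction`` is a unit-normalized (x, y, z) axis; the cylinder starts
    slightly inside the soma surface so soma and dendrite are connected.
    """

    direction: Tuple[float, float, float] = (0.834, -0.552, 0.0)
    length_um: float = 2.2
    radius_um: float = 0.35
    taper: float = 0.35  # tip radius = radius * (1 - taper)


@dataclass(frozen=True)
class NucleusSpec:
    center_um: Tuple[float, float, float]
    semi_axes_um: Tuple[float, float, float]
    invagination_amplitude: float = 0.08
    invagination_order: int = 3


@dataclass(frozen=True)
class VolumeLaw:
    """Log-normal law over punctum volume (μm³), truncated to a diameter range.

    Defaults give a right-skewed distribution with mean diameter ≈ 250 nm,
    truncated to the 100–500 nm range reported for human early endosomes
    by electron microscopy.
    """

    mu_log: float = math.log(0.008)
    sigma_log: float = 0.45
    d_min_um: float = 0.1
    d_max_um: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")
        if not 0 < self.d_min_um < self.d_max_um:
            raise ValueError("need 0 < d_min < d_max")

    @property
    def v_min_um3(self) -> float:
        return math.pi * self.d_min_um**3 / 6.0

    @property
    def v_max_um3(self) -> float:
        return math.pi * self.d_max_um**3 / 6.0

    def truncated_mean_um3(self) -> float:
        """Analytic mean of the truncated log-normal volume law."""
        a = (math.log(self.v_min_um3) - self.mu_log) / self.sigma_log
        b = (math.log(self.v_max_um3) - self.mu_log) / self.sigma_log
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        num = stats.norm.cdf(b - self.sigma_log) - stats.norm.cdf(a - self.sigma_log)
        return math.exp(self.mu_log + 0.5 * self.sigma_log**2) * num / z


@dataclass(frozen=True)
class ClusteringSpec:
    """Thomas-process style clustered placement (optional)."""

    n_parents: int = 3
    sigma_um: float = 0.5


@dataclass(frozen=True)
class AutofluorescenceSpec:
    """Lipofuscin-like granules bleeding into the imaging channels.

    Quenching in real tissue leaves low residual autofluorescence; the
    bleed fractions are free parameters of the simulation.
    """

    n_granules: int = 3
    radius_um: Tuple[float, float] = (0.25, 0.4)  # sampled uniformly
    amplitude: float = 500.0
    bleed_nuclear: float = 0.3
    bleed_somatodendritic: float = 0.3
    bleed_puncta: float = 0.3


@dataclass(frozen=True)
class NoiseSpec:
    """Poisson shot noise at a photon scale giving peak SNR ≈ sqrt(peak_photons)."""

    enabled: bool = True
    peak_photons: float = 100.0
    read_noise_sd: float = 2.0


@dataclass(frozen=True)
class PhantomSpec:
    profile: AcquisitionProfile
    soma: EllipsoidSpec
    dendrite: DendriteSpec
    nucleus: NucleusSpec
    n_distractor_nuclei: int = 2
    n_disconnected_neurites: int = 3
    puncta_count_somatodendritic: int = 12
    puncta_count_perinuclear: int = 6
    volume_law: VolumeLaw = field(default_factory=VolumeLaw)
    clustering: Optional[ClusteringSpec] = None
    autofluorescence: AutofluorescenceSpec = field(default_factory=AutofluorescenceSpec)
    psf_sigma_um: Tuple[float, float, float] = (0.08, 0.08, 0.15)  # (x, y, z)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    min_separation_um: float = 0.6
    placement_margin_um: float = 0.25  # interior margin within the MAP2 region
    perinuclear_shell_um: float = 0.3  # shell thickness outside the nucleus
    shell_band_um: Tuple[float, float] = (0.05, 0.25)  # placement band inside shell
    map2_exclusion_um: float = 0.55  # perinuclear zone without MAP2 signal
    z_face_margin_um: float = 0.1  # extra clearance of spheres from stack z faces
    amplitude_puncta: float = 1000.0
    amplitude_somatodendritic: float = 600.0
    amplitude_nuclear: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.psf_sigma_um) <= 0:
            raise ValueError("psf sigmas must be positive")
        for name in (
            "n_distractor_nuclei",
            "n_disconnected_neurites",
            "puncta_count_somatodendritic",
            "puncta_count_perinuclear",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PhantomTruth:
    """Ground truth emitted alongside the rendered stack.

    ``puncta`` has one row per true punctum: id, cx_um, cy_um, cz_um,
    volume_um3, diameter_um, compartment (somatodendritic | perinuclear).
    ``masks`` holds boolean (z, y, x) structure masks:
    soma, dendrite, nucleus, somatodendritic_region (MAP2 signal region),
    perinuclear_region (shell outside the nucleus), distractor_nuclei,
    neurite_fragments, granules.
    """

    puncta: pd.DataFrame
    masks: Dict[str, np.ndarray]
    spacing: VoxelSpacing


DEFAULT_ROLES = ChannelRoleMap(nuclear=0, somatodendritic=1, puncta=2)


def default_spec(seed: int = 0) -> PhantomSpec:
    """Desk-scale default phantom: 256×256 plane at the protocol voxel
    spacing (0.03, 0.03, 0.13) μm with 14 z planes."""
    profile = AcquisitionProfile(
        plane_shape=(256, 256),
        n_z=14,
        spacing=VoxelSpacing(dx=0.03, dy=0.03, dz=0.13),
    )
    # field is 7.68 × 7.68 × 1.82 μm
    soma = EllipsoidSpec(center_um=(3.3, 4.1, 0.91), semi_axes_um=(2.6, 2.2, 0.68))
    nucleus = NucleusSpec(center_um=(3.3, 4.1, 0.91), semi_axes_um=(0.95, 0.8, 0.42))
    return PhantomSpec(profile=profile, soma=soma, dendrite=DendriteSpec(), nucleus=nucleus, seed=seed)


# ---------------------------------------------------------------------------
# Geometry helpers (voxel-center coordinate convention: (i + 0.5) * spacing)


def _grids(shape_zyx: Tuple[int, int, int], spacing: VoxelSpacing):
    nz, ny, nx = shape_zyx
    z = (np.arange(nz) + 0.5) * spacing.dz
    y = (np.arange(ny) + 0.5) * spacing.dy
    x = (np.arange(nx) + 0.5) * spacing.dx
    return np.meshgrid(z, y, x, indexing="ij", sparse=True)


def _ellipsoid_mask(grids, ell: EllipsoidSpec) -> np.ndarray:
    Z, Y, X = grids
    cx, cy, cz = ell.center_um
    sx, sy, sz = ell.semi_axes_um
    return ((X - cx) / sx) ** 2 + ((Y - cy) / sy) ** 2 + ((Z - cz) / sz) ** 2 <= 1.0


def _nucleus_mask(grids, nuc: NucleusSpec) -> np.ndarray:
    """Ellipsoid with a low-order azimuthal-harmonic radial perturbation,
    giving the non-convex invaginated contour characteristic of neuronal
    nuclei."""
    Z, Y, X = grids
    cx, cy, cz = nuc.center_um
    sx, sy, sz = nuc.semi_axes_um
    px = (X - cx) / sx
    py = (Y - cy) / sy
    pz = (Z - cz) / sz
    rho = np.sqrt(px**2 + py**2 + pz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.where(rho > 0, pz / np.maximum(rho, 1e-12), 0.0)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, 1.0))
    phi = np.arctan2(py, px)
    m = nuc.invagination_order
    pert = nuc.invagination_amplitude * np.cos(m * phi) * sin_t**m
    return rho <= 1.0 + pert


def _cylinder_mask(grids, start_um, direction, length_um, r0_um, r1_um) -> np.ndarray:
    """Tapering cylinder from start along unit direction."""
    Z, Y, X = grids
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    dx_ = X - start_um[0]
    dy_ = Y - start_um[1]
    dz_ = Z - start_um[2]
    t = dx_ * u[0] + dy_ * u[1] + dz_ * u[2]
    rad2 = (dx_ - t * u[0]) ** 2 + (dy_ - t * u[1]) ** 2 + (dz_ - t * u[2]) ** 2
    with np.errstate(invalid="ignore"):
        r_here = r0_um + (r1_um - r0_um) * np.clip(t / max(length_um, 1e-9), 0.0, 1.0)
    return (t >= 0) & (t <= length_um) & (rad2 <= r_here**2)


# ---------------------------------------------------------------------------
# Volume sampling and placement


def sample_volumes(law: VolumeLaw, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` punctum volumes (μm³) from the truncated log-normal law."""
    a = (math.log(law.v_min_um3) - law.mu_log) / law.sigma_log
    b = (math.log(law.v_max_um3) - law.mu_log) / law.sigma_log
    logs = stats.truncnorm.rvs(a, b, loc=law.mu_log, scale=law.sigma_log, size=n, random_state=rng)
    return np.exp(logs)


def _place_points(
    mask: np.ndarray,
    radii_um: np.ndarray,
    spacing: VoxelSpacing,
    rng: np.random.Generator,
    min_separation_um: float,
    z_extent_um: float,
    z_face_margin_um: float,
    existing: Sequence[Tuple[float, float, float, float]] = (),
    clustering: Optional[ClusteringSpec] = None,
    max_attempts: int = 4000,
) -> np.ndarray:
    """Place sphere centers inside ``mask`` with a hard minimum separation.

    ``existing`` holds (x, y, z, clearance) tuples that new points must
    also clear. Returns (n, 3) array of (x, y, z) μm. Raises
    :class:`PlacementError` when a point cannot be placed.
    """
    n = len(radii_um)
    if n == 0:
        return np.zeros((0, 3))
    candidates = np.argwhere(mask)
    if candidates.size == 0:
        raise PlacementError("placement mask is empty")
    d_zyx = np.array(spacing.zyx)
    accepted: List[np.ndarray] = []
    parents = None
    if clustering is not None and clustering.n_parents > 0:
        pick = rng.integers(0, len(candidates), size=clustering.n_parents)
        parents = (candidates[pick] + 0.5) * d_zyx  # (z, y, x) μm

    nz, ny, nx = mask.shape
    for i in range(n):
        r = float(radii_um[i])
        placed = False
        for _ in range(max_attempts):
            if parents is not None:
                p = parents[rng.integers(0, len(parents))]
                cand = p + rng.normal(0.0, clustering.sigma_um, size=3)
                idx = np.floor(cand / d_zyx).astype(int)
                if np.any(idx < 0) or idx[0] >= nz or idx[1] >= ny or idx[2] >= nx:
                    continue
                if not mask[tuple(idx)]:
                    continue
                pos_zyx = cand
            else:
                idx = candidates[rng.integers(0, len(candidates))]
                pos_zyx = (idx + rng.uniform(0.0, 1.0, size=3)) * d_zyx
            z = pos_zyx[0]
            if z < r + z_face_margin_um or z > z_extent_um - r - z_face_margin_um:
                continue
            p_xyz = np.array([pos_zyx[2], pos_zyx[1], pos_zyx[0]])
            ok = True
            for q in accepted:
                if np.linalg.norm(p_xyz - q) < min_separation_um:
                    ok = False
                    break
            if ok:
                for (ex, ey, ez, clr) in existing:
                    if np.linalg.norm(p_xyz - np.array([ex, ey, ez])) < clr:
                        ok = False
                        break
            if ok:
                accepted.append(p_xyz)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place punctum {i + 1}/{n} after {max_attempts} attempts"
            )
    return np.asarray(accepted)


# ---------------------------------------------------------------------------
# Generator


def _physical_extent(spec: PhantomSpec) -> Tuple[float, float, float]:
    ny, nx = spec.profile.plane_shape
    sp = spec.profile.spacing
    return (nx * sp.dx, ny * sp.dy, spec.profile.n_z * sp.dz)  # (X, Y, Z) μm


def _place_distractors(spec: PhantomSpec, grids, soma_dendrite: np.ndarray, rng):
    """Random non-neuronal nuclei and disconnected neurite fragments that
    must stay clear of the neuron itself."""
    ext_x, ext_y, ext_z = _physical_extent(spec)
    sp = spec.profile.spacing
    # distance (μm) from every voxel to the neuron, for clearance checks
    dist_to_neuron = ndimage.distance_transform_edt(~soma_dendrite, sampling=sp.zyx)

    def clear_at(x, y, z, clearance):
        ix = min(int(x / sp.dx), dist_to_neuron.shape[2] - 1)
        iy = min(int(y / sp.dy), dist_to_neuron.shape[1] - 1)
        iz = min(int(z / sp.dz), dist_to_neuron.shape[0] - 1)
        return dist_to_neuron[iz, iy, ix] >= clearance

    shape = soma_dendrite.shape
    distractors = np.zeros(shape, dtype=np.int32)
    centers = []
    semi = (0.75, 0.65, 0.4)
    for k in range(spec.n_distractor_nuclei):
        for _ in range(400):
            x = rng.uniform(semi[0] + 0.1, ext_x - semi[0] - 0.1)
            y = rng.uniform(semi[1] + 0.1, ext_y - semi[1] - 0.1)
            z = rng.uniform(0.45, ext_z - 0.45)
            if not clear_at(x, y, z, max(semi) + 0.3):
                continue
            if any(np.hypot(x - cx, y - cy) < 2.0 for cx, cy, _ in centers):
                continue
            m = _ellipsoid_mask(grids, EllipsoidSpec((x, y, z), semi))
            distractors[m] = k + 1
            centers.append((x, y, z))
            break
    fragments = np.zeros(shape, dtype=bool)
    frag_centers = []
    for _ in range(spec.n_disconnected_neurites):
        for _ in range(400):
            length = rng.uniform(0.8, 1.4)
            theta = rng.uniform(0, 2 * math.pi)
            u = (math.cos(theta), math.sin(theta), 0.0)
            x = rng.uniform(0.4, ext_x - 0.4 - length)
            y = rng.uniform(0.4, ext_y - 0.4)
            z = rng.uniform(0.4, ext_z - 0.4)
            end = (x + u[0] * length, y + u[1] * length, z)
            if not (0.3 < end[0] < ext_x - 0.3 and 0.3 < end[1] < ext_y - 0.3):
                continue
            mid = (x + u[0] * length / 2, y + u[1] * length / 2, z)
            if not all(clear_at(px, py, pz, 0.55) for px, py, pz in (( x, y, z), mid, end)):
                continue
            if any(np.hypot(mid[0] - fx, mid[1] - fy) < 1.5 for fx, fy in frag_centers):
                continue
            fragments |= _cylinder_mask(grids, (x, y, z), u, length, 0.22, 0.18)
            frag_centers.append((mid[0], mid[1]))
            break
    return distractors, fragments, dist_to_neuron


def generate_phantom(spec: PhantomSpec) -> Tuple[ImageStack, PhantomTruth]:
    """Render a phantom stack and its ground truth.

    The puncta channel is the sum of analytic sphere-overlap rasterizations
    at the true volumes, convolved with the Gaussian PSF and (optionally)
    shot-noised; the MAP2-like channel covers the soma ∪ dendrite minus a
    perinuclear exclusion zone, plus disconnected fragments; the nuclear
    channel covers the neuronal and distractor nuclei.
    """
    rng = np.random.default_rng(spec.seed)
    sp = spec.profile.spacing
    ny, nx = spec.profile.plane_shape
    shape = (spec.profile.n_z, ny, nx)
    grids = _grids(shape, sp)
    ext_x, ext_y, ext_z = _physical_extent(spec)

    # -- structures -------------------------------------------------------
    soma = _ellipsoid_mask(grids, spec.soma)
    nucleus = _nucleus_mask(grids, spec.nucleus)
    # dendrite starts just inside the soma surface along its axis
    u = np.asarray(spec.dendrite.direction, dtype=float)
    u = u / np.linalg.norm(u)
    sx, sy, sz = spec.soma.semi_axes_um
    t_surf = 1.0 / math.sqrt((u[0] / sx) ** 2 + (u[1] / sy) ** 2 + (u[2] / sz) ** 2 + 1e-300)
    start = tuple(np.asarray(spec.soma.center_um) + u * (t_surf - 0.4))
    dendrite = _cylinder_mask(
        grids,
        start,
        u,
        spec.dendrite.length_um + 0.4,
        spec.dendrite.radius_um,
        spec.dendrite.radius_um * (1.0 - spec.dendrite.taper),
    )
    soma_dendrite = soma | dendrite

    nucleus_dist = ndimage.distance_transform_edt(~nucleus, sampling=sp.zyx)
    map2_region = soma_dendrite & (nucleus_dist > spec.map2_exclusion_um)
    perinuclear_region = (nucleus_dist > 0) & (nucleus_dist <= spec.perinuclear_shell_um)

    distractors, fragments, _ = _place_distractors(spec, grids, soma_dendrite, rng)

    # -- autofluorescent granules ----------------------------------------
    granule_intensity = np.zeros(shape, dtype=np.float64)
    granule_mask = np.zeros(shape, dtype=bool)
    granule_pts: List[Tuple[float, float, float, float]] = []
    af = spec.autofluorescence
    if af.n_granules > 0:
        # keep granules clear of both analysis ROIs: they model neuropil
        # lipofuscin outside the selected neuron
        roi_union = map2_region | (nucleus_dist <= spec.perinuclear_shell_um + 0.3)
        clear = ndimage.distance_transform_edt(~roi_union, sampling=sp.zyx)
        for _ in range(af.n_granules):
            r = rng.uniform(*af.radius_um)
            for _ in range(600):
                x = rng.uniform(r + 0.1, ext_x - r - 0.1)
                y = rng.uniform(r + 0.1, ext_y - r - 0.1)
                z = rng.uniform(r + 0.1, ext_z - r - 0.1)
                ix = min(int(x / sp.dx), nx - 1)
                iy = min(int(y / sp.dy), ny - 1)
                iz = min(int(z / sp.dz), shape[0] - 1)
                if clear[iz, iy, ix] < r + 0.2:
                    continue
                if any(
                    np.linalg.norm(np.array([x, y, z]) - np.array(g[:3])) < r + g[3] + 0.3
                    for g in granule_pts
                ):
                    continue
                add_sphere_occupancy(granule_intensity, sp, (x, y, z), r, af.amplitude)
                granule_mask |= _ellipsoid_mask(grids, EllipsoidSpec((x, y, z), (r, r, r)))
                granule_pts.append((x, y, z, r))
                break

    # -- puncta -----------------------------------------------------------
    n_sd = spec.puncta_count_somatodendritic
    n_pn = spec.puncta_count_perinuclear
    volumes = sample_volumes(spec.volume_law, n_sd + n_pn, rng)
    radii = (3.0 * volumes / (4.0 * math.pi)) ** (1.0 / 3.0)

    # somatodendritic puncta sit well interior to the MAP2 region so the
    # masked channel retains essentially all of their blurred flux
    interior = ndimage.distance_transform_edt(map2_region, sampling=sp.zyx)
    sd_mask = interior >= spec.placement_margin_um
    band_lo, band_hi = spec.shell_band_um
    pn_mask = (nucleus_dist >= band_lo) & (nucleus_dist <= band_hi)

    granule_clear = [(g[0], g[1], g[2], g[3] + 0.45) for g in granule_pts]
    pts_sd = _place_points(
        sd_mask, radii[:n_sd], sp, rng, spec.min_separation_um, ext_z,
        spec.z_face_margin_um, existing=granule_clear, clustering=spec.clustering,
    )
    pn_existing = granule_clear + [
        (p[0], p[1], p[2], spec.min_separation_um) for p in pts_sd
    ]
    pts_pn = _place_points(
        pn_mask, radii[n_sd:], sp, rng, spec.min_separation_um, ext_z,
        spec.z_face_margin_um, existing=pn_existing,
    )

    ch_puncta = np.zeros(shape, dtype=np.float64)
    centers = np.concatenate([pts_sd, pts_pn]) if (n_sd + n_pn) else np.zeros((0, 3))
    for (x, y, z), r in zip(centers, radii):
        add_sphere_occupancy(ch_puncta, sp, (x, y, z), r, spec.amplitude_puncta)

    # -- compose channels -------------------------------------------------
    ch_nuclear = spec.amplitude_nuclear * ((nucleus | (distractors > 0)).astype(np.float64))
    ch_map2 = spec.amplitude_somatodendritic * ((map2_region | fragments).astype(np.float64))
    ch_nuclear += af.bleed_nuclear * granule_intensity
    ch_map2 += af.bleed_somatodendritic * granule_intensity
    ch_puncta += af.bleed_puncta * granule_intensity

    sig_vox = (
        spec.psf_sigma_um[2] / sp.dz,
        spec.psf_sigma_um[1] / sp.dy,
        spec.psf_sigma_um[0] / sp.dx,
    )
    channels = []
    for ch in (ch_nuclear, ch_map2, ch_puncta):
        channels.append(ndimage.gaussian_filter(ch, sigma=sig_vox, mode="constant"))

    if spec.noise.enabled:
        noisy = []
        for ch in channels:
            m = ch.max()
            scale = spec.noise.peak_photons / m if m > 0 else 1.0
            counts = rng.poisson(ch * scale).astype(np.float64)
            counts += rng.normal(0.0, spec.noise.read_noise_sd, size=ch.shape)
            noisy.append(np.clip(counts, 0.0, None))
        channels = noisy

    stack = ImageStack(
        intensities=np.stack(channels).astype(np.float32),
        spacing=sp,
        roles=DEFAULT_ROLES,
        image_id=f"phantom-{spec.seed}",
    )

    comp = ["somatodendritic"] * n_sd + ["perinuclear"] * n_pn
    truth_df = pd.DataFrame(
        {
            "id": np.arange(n_sd + n_pn, dtype=int),
            "cx_um": centers[:, 0] if len(centers) else np.array([]),
            "cy_um": centers[:, 1] if len(centers) else np.array([]),
            "cz_um": centers[:, 2] if len(centers) else np.array([]),
            "volume_um3": volumes,
            "diameter_um": 2.0 * radii,
            "compartment": comp,
        }
    )
    truth = PhantomTruth(
        puncta=truth_df,
        masks={
            "soma": soma,
            "dendrite": dendrite,
            "nucleus": nucleus,
            "somatodendritic_region": map2_region,
            "perinuclear_region": perinuclear_region,
            "distractor_nuclei": distractors > 0,
            "neurite_fragments": fragments,
            "granules": granule_mask,
        },
        spacing=sp,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Cohort convenience


def generate_cohort(
    out_dir: os.PathLike | str,
    n_cases: int = 3,
    images_per_case: int = 8,
    seed: int = 0,
    base_spec: Optional[PhantomSpec] = None,
) -> List[dict]:
    """Write a synthetic cohort of phantom stacks + truth tables to disk.

    Returns a roster of dicts (path, case_id, image_id) suitable for a
    pipeline config. Per-image seeds are derived deterministically from
    ``seed``.
    """
    os.makedirs(out_dir, exist_ok=True)
    base = base_spec if base_spec is not None else default_spec()
    master = np.random.default_rng(seed)
    roster = []
    for c in range(n_cases):
        case_id = f"case{c + 1:02d}"
        for i in range(images_per_case):
            image_id = f"{case_id}_img{i + 1:02d}"
            sub_seed = int(master.integers(0, 2**31 - 1))
            spec = replace(base, seed=sub_seed)
            stack, truth = generate_phantom(spec)
            stack.case_id = case_id
            stack.image_id = image_id
            path = os.path.join(out_dir, f"{image_id}.ome.tif")
            write_stack(stack, path)
            truth.puncta.to_csv(os.path.join(out_dir, f"{image_id}_truth_puncta.csv"), index=False)
            roster.append({"path": path, "case_id": case_id, "image_id": image_id})
    return roster
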