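"""Config-driven batch orchestration of the two-stage analysis.

Stage 1 ("batch 1") builds and QCs the neuronal ROIs and writes them as
editable 8-bit TIFF masks; stage 2 ("batch 2") reloads the masks
(possibly hand-edited in between — the ``pause_for_edit`` point), masks
the puncta channel per ROI, runs both detection modes, and aggregates
per-image and per-case statistics. Failures are isolated per image:
one unreadable or QC-failing stack never aborts the batch.

No pipeline stage consumes randomness on fixed input; two runs over the
same files produce byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .morphostats import summarize_case, summarize_image
from .puncta import (
    PunctaFilter,
    SpotsParams,
    SurfaceParams,
    apply_filter,
    detect_spots_mode,
    detect_surface_mode,
    match_modes,
)
from .restoration import DeconvolutionParams, richardson_lucy
from .roi import (
    QCConfig,
    RoiSelectionError,
    SegmentationError,
    SegmentationParams,
    load_mask,
    mask_channel,
    qc_neuron,
    refine_perinuclear,
    refine_somatodendritic,
    segment_nuclei,
    segment_somatodendritic,
)
from .stack_io import ChannelRoleMap, ImageStack, VoxelSpacing, read_stack, write_mask

log = logging.getLogger("endopuncta.pipeline")

ROLES = ("somatodendritic", "perinuclear")


@dataclass(frozen=True)
class RosterEntry:
    path: str
    case_id: str
    image_id: str


@dataclass
class PipelineConfig:
    roster: List[RosterEntry]
    out_dir: str
    roles: ChannelRoleMap = field(default_factory=lambda: ChannelRoleMap(0, 1, 2))
    spacing_override: Optional[VoxelSpacing] = None
    deconvolve_enabled: bool = False
    deconvolve: DeconvolutionParams = field(default_factory=DeconvolutionParams)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    qc: QCConfig = field(default_factory=QCConfig)
    surface: SurfaceParams = field(default_factory=SurfaceParams)
    spots: SpotsParams = field(default_factory=SpotsParams)
    spots_diameter_range_um: Tuple[float, float] = (0.1, 0.5)
    puncta_filter: PunctaFilter = field(default_factory=PunctaFilter)
    k_neighbors: int = 3
    match_tolerance_um: float = 0.3
    seed: int = 0
    pause_for_edit: bool = False

    def __post_init__(self) -> None:
        if not self.roster:
            raise ValueError("roster must be non-empty")
        ids = [e.image_id for e in self.roster]
        if len(set(ids)) != len(ids):
            raise ValueError("image ids in the roster must be unique")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        d = {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}
        d["roster"] = [dataclasses.asdict(e) for e in self.roster]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def tup(v):
            return tuple(v) if isinstance(v, list) else v

        kw = dict(d)
        kw["roster"] = [RosterEntry(**e) for e in d["roster"]]
        if d.get("roles"):
            kw["roles"] = ChannelRoleMap(**d["roles"])
        if d.get("spacing_override"):
            kw["spacing_override"] = VoxelSpacing(**d["spacing_override"])
        for name, typ in (
            ("deconvolve", DeconvolutionParams),
            ("segmentation", SegmentationParams),
            ("qc", QCConfig),
            ("surface", SurfaceParams),
            ("spots", SpotsParams),
            ("puncta_filter", PunctaFilter),
        ):
            if d.get(name) is not None and not isinstance(d[name], typ):
                kw[name] = typ(**{k: tup(v) for k, v in d[name].items()})
        kw["spots_diameter_range_um"] = tup(d.get("spots_diameter_range_um", (0.1, 0.5)))
        return cls(**kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Manifest helpers


def _new_manifest(config: PipelineConfig, batch: str) -> dict:
    return {
        "software": f"endopuncta {__version__}",
        "batch": batch,
        "seed": config.seed,
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict(),
        "images": {},
    }


def _write_manifest(manifest: dict, out_dir: str, name: str) -> None:
    with open(os.path.join(out_dir, name), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _mask_path(out_dir: str, image_id: str, role: str) -> str:
    return os.path.join(out_dir, "masks", f"{image_id}_{role}.tif")


def _load_stack(entry: RosterEntry, config: PipelineConfig) -> ImageStack:
    stack = read_stack(
        entry.path,
        roles=config.roles,
        spacing_override=config.spacing_override,
        case_id=entry.case_id,
        image_id=entry.image_id,
    )
    if config.deconvolve_enabled:
        channels = [
            richardson_lucy(stack.intensities[c], stack.spacing, config.deconvolve)
            for c in range(stack.n_channels)
        ]
        stack = ImageStack(
            intensities=np.stack(channels).astype(np.float32),
            spacing=stack.spacing,
            roles=stack.roles,
            case_id=stack.case_id,
            image_id=stack.image_id,
        )
    return stack


# ---------------------------------------------------------------------------
# Batch 1: ROI creation + refinement + masking QC


def run_batch1(config: PipelineConfig) -> dict:
    """Create, refine, QC and persist both ROIs for every roster image.

    Returns the run manifest. Per-image outcomes: ``completed``,
    ``qc-excluded`` or ``errored``; failures never abort the batch.
    """
    os.makedirs(os.path.join(config.out_dir, "masks"), exist_ok=True)
    manifest = _new_manifest(config, "batch1")
    qc_rows = []
    for entry in config.roster:
        t0 = time.perf_counter()
        record: Dict[str, object] = {"case_id": entry.case_id, "stages": {}}
        somato = perinuc = None
        try:
            stack = _load_stack(entry, config)
            record["stages"]["read"] = "ok"
            try:
                nuclei = segment_nuclei(stack, config.segmentation)
                record["stages"]["segment_nuclei"] = f"ok ({int(nuclei.max())} components)"
            except SegmentationError as e:
                nuclei = None
                record["stages"]["segment_nuclei"] = f"failed: {e}"
            try:
                raw = segment_somatodendritic(stack, config.segmentation)
                record["stages"]["segment_somatodendritic"] = "ok"
                if nuclei is not None:
                    somato = refine_somatodendritic(raw, nuclei > 0)
                    record["stages"]["refine_somatodendritic"] = "ok"
            except (SegmentationError, RoiSelectionError) as e:
                record["stages"]["refine_somatodendritic"] = f"failed: {e}"
            if nuclei is not None and somato is not None:
                try:
                    perinuc = refine_perinuclear(
                        nuclei, somato,
                        dilation_um=config.segmentation.perinuclear_dilation_um,
                    )
                    record["stages"]["refine_perinuclear"] = "ok"
                except RoiSelectionError as e:
                    record["stages"]["refine_perinuclear"] = f"failed: {e}"

            report = qc_neuron(somato, perinuc, config.qc)
            if somato is not None:
                write_mask(somato, _mask_path(config.out_dir, entry.image_id, "somatodendritic"))
            if perinuc is not None:
                write_mask(perinuc, _mask_path(config.out_dir, entry.image_id, "perinuclear"))
                if perinuc.seed_voxels is not None:
                    write_mask(perinuc.seed_voxels,
                               _mask_path(config.out_dir, entry.image_id, "nucleus"))
            qc_rows.append(
                {
                    "case_id": entry.case_id,
                    "image_id": entry.image_id,
                    "qc_passed": report.passed,
                    **{f"check_{k}": v for k, v in report.checks.items()},
                    "reasons": "; ".join(report.reasons),
                }
            )
            record["status"] = "completed" if report.passed else "qc-excluded"
            record["qc_passed"] = report.passed
            record["reasons"] = report.reasons
        except Exception as e:  # unreadable entry → errored, batch continues
            log.warning("batch1: %s errored: %s", entry.image_id, e)
            record["status"] = "errored"
            record["error"] = str(e)
            qc_rows.append(
                {"case_id": entry.case_id, "image_id": entry.image_id,
                 "qc_passed": False, "reasons": f"errored: {e}"}
            )
        record["duration_s"] = round(time.perf_counter() - t0, 3)
        manifest["images"][entry.image_id] = record
        log.info("batch1 %s: %s", entry.image_id, record["status"])
    pd.DataFrame(qc_rows).to_csv(os.path.join(config.out_dir, "qc.csv"), index=False)
    _write_manifest(manifest, config.out_dir, "manifest_batch1.json")
    return manifest


# ---------------------------------------------------------------------------
# Batch 2: puncta analysis per ROI


def _analyze_image(stack: ImageStack, roi, config: PipelineConfig):
    masked = mask_channel(stack, roi)
    surface = detect_surface_mode(masked, stack.spacing, config.surface, roi=roi)
    surface = apply_filter(surface, config.puncta_filter)
    spots = detect_spots_mode(masked, stack.spacing, config.spots_diameter_range_um, config.spots)
    match = match_modes(surface, spots, config.match_tolerance_um)
    summary = summarize_image(
        surface, roi, k=config.k_neighbors,
        case_id=stack.case_id, image_id=stack.image_id, roi_role=roi.role,
    )
    return surface, spots, match, summary


def run_batch2(config: PipelineConfig, masks_dir: Optional[str] = None) -> dict:
    """Analyze the masked puncta channel of every batch-1-completed image
    in both ROIs and both modes, then aggregate image and case summaries.

    ``masks_dir`` defaults to ``<out_dir>/masks`` and may point at
    hand-edited mask TIFFs reloaded after the pause-for-edit step.
    Images whose batch-1 QC failed are skipped with a recorded reason.
    """
    masks_dir = masks_dir or os.path.join(config.out_dir, "masks")
    manifest = _new_manifest(config, "batch2")
    b1_path = os.path.join(config.out_dir, "manifest_batch1.json")
    b1_status: Dict[str, str] = {}
    if os.path.exists(b1_path):
        with open(b1_path) as fh:
            b1 = json.load(fh)
        b1_status = {k: v.get("status", "") for k, v in b1["images"].items()}

    puncta_rows, spot_rows, match_rows, image_summaries = [], [], [], []
    for entry in config.roster:
        t0 = time.perf_counter()
        record: Dict[str, object] = {"case_id": entry.case_id, "stages": {}}
        status_b1 = b1_status.get(entry.image_id, "completed")
        if status_b1 != "completed":
            record["status"] = "qc-excluded" if status_b1 == "qc-excluded" else "errored"
            record["reasons"] = [f"excluded in batch 1 ({status_b1})"]
            manifest["images"][entry.image_id] = record
            log.info("batch2 %s: skipped (%s)", entry.image_id, status_b1)
            continue
        try:
            stack = _load_stack(entry, config)
            for role in ROLES:
                path = os.path.join(masks_dir, f"{entry.image_id}_{role}.tif")
                if not os.path.exists(path):
                    raise FileNotFoundError(f"missing {role} mask: {path}")
                roi = load_mask(path, stack.spacing, role)
                surface, spots, match, summary = _analyze_image(stack, roi, config)
                surface = surface.assign(
                    case_id=entry.case_id, image_id=entry.image_id,
                    roi_volume_um3=roi.volume_um3,
                )
                spots = spots.assign(
                    case_id=entry.case_id, image_id=entry.image_id, roi_role=role
                )
                puncta_rows.append(surface)
                spot_rows.append(spots)
                match_rows.append(
                    {
                        "case_id": entry.case_id,
                        "image_id": entry.image_id,
                        "roi_role": role,
                        "n_surface": match.n_surface,
                        "n_spots": match.n_spots,
                        "n_matched": match.n_matched,
                        "frac_surface_matched": match.frac_surface_matched,
                        "frac_spots_matched": match.frac_spots_matched,
                    }
                )
                image_summaries.append(summary)
                record["stages"][role] = f"ok ({len(surface)} puncta, {len(spots)} spots)"
            record["status"] = "completed"
        except Exception as e:
            log.warning("batch2: %s errored: %s", entry.image_id, e)
            record["status"] = "errored"
            record["error"] = str(e)
        record["duration_s"] = round(time.perf_counter() - t0, 3)
        manifest["images"][entry.image_id] = record
        log.info("batch2 %s: %s", entry.image_id, record["status"])

    os.makedirs(config.out_dir, exist_ok=True)
    puncta = (
        pd.concat(puncta_rows, ignore_index=True) if puncta_rows else pd.DataFrame()
    )
    puncta.to_csv(os.path.join(config.out_dir, "puncta.csv"), index=False)
    spots_df = pd.concat(spot_rows, ignore_index=True) if spot_rows else pd.DataFrame()
    spots_df.to_csv(os.path.join(config.out_dir, "spots.csv"), index=False)
    pd.DataFrame(match_rows).to_csv(os.path.join(config.out_dir, "mode_match.csv"), index=False)
    img_df = (
        pd.concat(image_summaries, ignore_index=True) if image_summaries else pd.DataFrame()
    )
    img_df.to_csv(os.path.join(config.out_dir, "image_summary.csv"), index=False)
    case_df = aggregate_cases(img_df)
    case_df.to_csv(os.path.join(config.out_dir, "case_summary.csv"), index=False)
    _write_manifest(manifest, config.out_dir, "manifest_batch2.json")
    return manifest


def aggregate_cases(image_summaries: pd.DataFrame) -> pd.DataFrame:
    """Case-level aggregation over per-image summaries (all cases)."""
    if len(image_summaries) == 0:
        return pd.DataFrame()
    out = [
        summarize_case(grp)
        for _, grp in image_summaries.groupby("case_id", sort=True)
    ]
    return pd.concat(out, ignore_index=True)


def run_all(config: PipelineConfig) -> dict:
    """Batch 1 followed by batch 2.

    With ``pause_for_edit`` the run stops after batch 1 so masks under
    ``<out_dir>/masks`` can be hand-edited; rerun batch 2 afterwards.
    With untouched masks the composition is identical to running the two
    batches separately.
    """
    m1 = run_batch1(config)
    if config.pause_for_edit:
        log.info(
            "paused after batch 1: edit masks under %s, then run batch2",
            os.path.join(config.out_dir, "masks"),
        )
        return {"batch1": m1, "batch2": None, "paused": True}
    m2 = run_batch2(config)
    return {"batch1": m1, "batch2": m2, "paused": False}


def reaggregate(puncta_csv: str, out_dir: str, k: int = 3) -> pd.DataFrame:
    """Recompute image and case summaries from an existing puncta table."""
    puncta = pd.read_csv(puncta_csv)
    summaries = []
    for (case_id, image_id, role), grp in puncta.groupby(
        ["case_id", "image_id", "roi_role"], sort=True
    ):
        summaries.append(
            summarize_image(
                grp.reset_index(drop=True),
                float(grp["roi_volume_um3"].iloc[0]),
                k=k, case_id=case_id, image_id=image_id, roi_role=role,
            )
        )
    img_df = pd.concat(summaries, ignore_index=True) if summaries else pd.DataFrame()
    os.makedirs(out_dir, exist_ok=True)
    img_df.to_csv(os.path.join(out_dir, "image_summary.csv"), index=False)
    case_df = aggregate_cases(img_df)
    case_df.to_csv(os.path.join(out_dir, "case_summary.csv"), index=False)
    return case_df
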