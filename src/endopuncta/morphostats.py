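"""Morphology and clustering statistics with per-image / per-case aggregation.

Implements the workflow's descriptive outputs: per-punctum mean
distance to the k nearest neighbours (k = 3 by default, a clustering
"tightness" readout), per-ROI puncta density, per-image volume
distribution summaries, and unweighted per-case aggregation where every
imaged neuron contributes equally.

Conventions: all distances are Euclidean in physical μm, computed
centroid-to-centroid within a single ROI of a single image; quartiles
use linear interpolation between order statistics; undefined statistics
(too few puncta) propagate as NaN.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .roi import RoiMask

IMAGE_SUMMARY_COLUMNS = [
    "case_id",
    "image_id",
    "roi_role",
    "n_puncta",
    "volume_mean_um3",
    "volume_sd_um3",
    "volume_median_um3",
    "volume_q1_um3",
    "volume_q3_um3",
    "volume_min_um3",
    "volume_max_um3",
    "density_per_um3",
    "mean_knn_um",
    "roi_volume_um3",
]

_CASE_METRICS = [
    "n_puncta",
    "volume_mean_um3",
    "volume_median_um3",
    "density_per_um3",
    "mean_knn_um",
    "roi_volume_um3",
]


def knn_mean_distance(centroids: np.ndarray | Sequence, k: int = 3) -> pd.DataFrame:
    """Mean Euclidean distance from each point to its k nearest others.

    Exact (KD-tree, no approximation). With fewer than k+1 points every
    result is undefined and returned as NaN. Deterministic under
    permutation of the input order (distances depend only on geometry).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pts = np.asarray(centroids, dtype=float).reshape(-1, 3)
    n = len(pts)
    out = pd.DataFrame({"id": np.arange(n), "k": k, "mean_knn_distance_um": np.nan})
    if n < k + 1:
        return out
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=k + 1)  # first neighbour is the point itself
    out["mean_knn_distance_um"] = dist[:, 1:].mean(axis=1)
    return out


def density(n_puncta: int, roi_volume_um3: float) -> float:
    """Puncta per μm³ of ROI."""
    if roi_volume_um3 <= 0:
        raise ValueError("ROI volume must be positive")
    if n_puncta < 0:
        raise ValueError("count must be non-negative")
    return n_puncta / roi_volume_um3


def summarize_image(
    table: pd.DataFrame,
    roi: RoiMask | float,
    k: int = 3,
    case_id: str = "",
    image_id: str = "",
    roi_role: Optional[str] = None,
) -> pd.DataFrame:
    """One-row per-image summary of a puncta table within one ROI.

    ``roi`` may be a :class:`RoiMask` or a plain ROI volume in μm³.
    An empty table yields n = 0, density 0 and NaN distribution stats.
    """
    roi_volume = roi if isinstance(roi, (int, float)) else roi.volume_um3
    if roi_role is not None:
        role = roi_role
    elif hasattr(roi, "role"):
        role = roi.role
    elif "roi_role" in table.columns and len(table):
        role = table["roi_role"].iloc[0]
    else:
        role = ""
    n = len(table)
    row = {
        "case_id": case_id,
        "image_id": image_id,
        "roi_role": role,
        "n_puncta": n,
        "volume_mean_um3": np.nan,
        "volume_sd_um3": np.nan,
        "volume_median_um3": np.nan,
        "volume_q1_um3": np.nan,
        "volume_q3_um3": np.nan,
        "volume_min_um3": np.nan,
        "volume_max_um3": np.nan,
        "density_per_um3": density(n, roi_volume),
        "mean_knn_um": np.nan,
        "roi_volume_um3": roi_volume,
    }
    if n:
        v = table["volume_um3"].to_numpy(dtype=float)
        row.update(
            volume_mean_um3=float(v.mean()),
            volume_sd_um3=float(v.std(ddof=1)) if n > 1 else np.nan,
            volume_median_um3=float(np.percentile(v, 50)),
            volume_q1_um3=float(np.percentile(v, 25)),
            volume_q3_um3=float(np.percentile(v, 75)),
            volume_min_um3=float(v.min()),
            volume_max_um3=float(v.max()),
        )
        knn = knn_mean_distance(table[["cx_um", "cy_um", "cz_um"]].to_numpy(), k=k)
        vals = knn["mean_knn_distance_um"].to_numpy()
        if np.any(np.isfinite(vals)):
            row["mean_knn_um"] = float(np.nanmean(vals))
    return pd.DataFrame([row], columns=IMAGE_SUMMARY_COLUMNS)


def summarize_case(images: pd.DataFrame) -> pd.DataFrame:
    """Per-case aggregation: unweighted mean and sd across that case's
    images, per ROI role — each imaged neuron contributes equally,
    regardless of how many puncta it holds."""
    if len(images) == 0:
        raise ValueError("need at least one image summary")
    if images["case_id"].nunique() > 1:
        raise ValueError(f"mixed case ids: {sorted(images['case_id'].unique())}")
    rows = []
    for role, grp in images.groupby("roi_role", sort=True):
        row = {"case_id": images["case_id"].iloc[0], "roi_role": role, "n_images": len(grp)}
        for metric in _CASE_METRICS:
            vals = grp[metric].to_numpy(dtype=float)
            row[f"{metric}_mean"] = float(np.nanmean(vals)) if np.any(np.isfinite(vals)) else np.nan
            finite = vals[np.isfinite(vals)]
            row[f"{metric}_sd"] = float(np.std(finite, ddof=1)) if len(finite) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def export_spatial(table: pd.DataFrame, color_by: str = "volume_um3", k: int = 3) -> pd.DataFrame:
    """Long-format spatial export (x, y, z, metric) for 3-D scatter tools.

    ``color_by = "mean_knn"`` derives the k-nearest-neighbour metric on
    the fly; any numeric column of the table is accepted otherwise.
    Row count equals the punctum count; undefined metric values stay NaN.
    """
    out = pd.DataFrame(
        {
            "x_um": table["cx_um"] if len(table) else pd.Series(dtype=float),
            "y_um": table["cy_um"] if len(table) else pd.Series(dtype=float),
            "z_um": table["cz_um"] if len(table) else pd.Series(dtype=float),
        }
    )
    if color_by == "mean_knn":
        if len(table):
            knn = knn_mean_distance(table[["cx_um", "cy_um", "cz_um"]].to_numpy(), k=k)
            out["mean_knn"] = knn["mean_knn_distance_um"].to_numpy()
        else:
            out["mean_knn"] = pd.Series(dtype=float)
        return out
    if color_by not in table.columns:
        raise KeyError(f"unknown metric {color_by!r}")
    out[color_by] = table[color_by].to_numpy() if len(table) else pd.Series(dtype=float)
    return out
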