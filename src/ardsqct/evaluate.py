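"""Segmentation agreement and method-comparison statistics.

Agreement between two binary masks is measured by intersection over union
(IoU, Jaccard index), per slice and per stacked volume, and profiled along
the cranio-caudal axis.  Quantities derived from two segmentations of the
same scans are compared by Bland-Altman analysis (bias and 1.96-SD limits
of agreement), ordinary least-squares regression, and a paired test that
uses Student's t when the paired differences look normal (Shapiro-Wilk,
alpha = 0.05) and the Wilcoxon signed-rank test otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "iou",
    "iou_per_volume",
    "craniocaudal_profile",
    "bland_altman",
    "linreg",
    "paired_compare",
    "AgreementReport",
    "agreement_report",
]


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Both masks empty is defined as perfect agreement (1.0): the methods
    agree the slice contains no lung.
    """
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def iou_per_volume(masks_a: np.ndarray, masks_b: np.ndarray) -> float:
    """Voxel-level IoU over whole stacked volumes (not the mean of slices)."""
    return iou(masks_a, masks_b)


def iou_per_volume_slicemean(masks_a: np.ndarray, masks_b: np.ndarray) -> float:
    """Alternative per-volume metric: mean of per-slice IoU values."""
    a = np.asarray(masks_a)
    b = np.asarray(masks_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(np.mean([iou(a[k], b[k]) for k in range(a.shape[0])]))


def slice_ious(masks_a: np.ndarray, masks_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice IoU plus a flag marking slices whose union is non-empty."""
    a = np.asarray(masks_a).astype(bool)
    b = np.asarray(masks_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    vals = np.array([iou(a[k], b[k]) for k in range(a.shape[0])])
    nonempty = np.array([(a[k] | b[k]).any() for k in range(a.shape[0])])
    return vals, nonempty


def craniocaudal_profile(
    per_subject: Mapping[str, Sequence[float]] | Mapping[str, np.ndarray],
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean IoU along the normalized cranio-caudal axis, binned across subjects.

    ``per_subject`` maps a subject id to its apex-to-base sequence of
    per-slice IoU values; entries that are NaN (e.g. slices where both
    masks are empty) are excluded.  Each subject's slice axis is normalized
    to [0, 1] before binning.  Returns columns
    (bin_center, mean_iou, sd_iou, n).
    """
    pos_all, val_all = [], []
    for _, vals in per_subject.items():
        vals = np.asarray(vals, dtype=float)
        k = len(vals)
        if k == 0:
            continue
        pos = np.zeros(k) if k == 1 else np.arange(k) / (k - 1)
        keep = ~np.isnan(vals)
        pos_all.append(pos[keep])
        val_all.append(vals[keep])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if not pos_all:
        return pd.DataFrame({"bin_center": centers, "mean_iou": np.nan, "sd_iou": np.nan, "n": 0})
    pos = np.concatenate(pos_all)
    val = np.concatenate(val_all)
    which = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    n = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = val[which == b]
        n[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            sd[b] = sel.std(ddof=1) if sel.size > 1 else 0.0
    return pd.DataFrame({"bin_center": centers, "mean_iou": mean, "sd_iou": sd, "n": n})


def bland_altman(x, y) -> dict:
    """Bland-Altman bias and 1.96-SD limits of agreement for paired values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "lo": bias - 1.96 * sd, "hi": bias + 1.96 * sd, "sd": sd}


def linreg(x, y) -> dict:
    """Ordinary least squares y ~ x; R^2 is the squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least three points")
    if np.var(x) == 0:
        raise ValueError("x is degenerate (zero variance)")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return {"slope": float(res.slope), "intercept": float(res.intercept), "r_squared": r2}


def paired_compare(x, y, alpha: float = 0.05) -> dict:
    """Paired two-tailed comparison with automatic test selection.

    Differences are screened with Shapiro-Wilk; normal-looking differences
    use the paired t test, otherwise the Wilcoxon signed-rank test.  All
    differences zero is reported as degenerate (perfect agreement).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 4:
        raise ValueError("need paired samples of equal length >= 4")
    d = y - x
    if np.all(d == 0):
        return {"test": "degenerate", "statistic": 0.0, "p": 1.0,
                "note": "all paired differences are zero"}
    sw_p = float(stats.shapiro(d).pvalue)
    if sw_p >= alpha:
        res = stats.ttest_rel(y, x)
        return {"test": "paired t", "statistic": float(res.statistic),
                "p": float(res.pvalue), "shapiro_p": sw_p}
    res = stats.wilcoxon(y, x)
    return {"test": "wilcoxon", "statistic": float(res.statistic),
            "p": float(res.pvalue), "shapiro_p": sw_p}


@dataclass
class AgreementReport:
    """Aggregated slice/volume agreement between two mask sets."""

    per_slice_iou: dict[str, list[float]]
    per_volume_iou: dict[str, float]
    slice_mean: float
    slice_sd: float
    volume_mean: float
    volume_sd: float
    profile: pd.DataFrame
    bland_altman_volume: dict | None = None
    regression_volume: dict | None = None
    paired_test_volume: dict | None = None

    def to_json(self, path) -> None:
        d = {
            "per_slice_iou": self.per_slice_iou,
            "per_volume_iou": self.per_volume_iou,
            "slice_mean": self.slice_mean,
            "slice_sd": self.slice_sd,
            "volume_mean": self.volume_mean,
            "volume_sd": self.volume_sd,
            "bland_altman_volume": self.bland_altman_volume,
            "regression_volume": self.regression_volume,
            "paired_test_volume": self.paired_test_volume,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def agreement_report(
    masks_a: Mapping[str, np.ndarray],
    masks_b: Mapping[str, np.ndarray],
    n_bins: int = 20,
    volume_metric: str = "voxel",
) -> AgreementReport:
    """Compare two mask sets (subject id -> 3-D mask) end to end.

    Per-slice IoU (slices with an empty union excluded from aggregation and
    profile), per-volume IoU (voxel-level by default, slice-mean by flag),
    the cranio-caudal profile, and — when there are at least four subjects —
    Bland-Altman, regression and a paired test on per-volume lung voxel
    counts.
    """
    if set(masks_a) != set(masks_b):
        raise ValueError("subject sets differ between the two mask collections")
    per_slice: dict[str, list[float]] = {}
    per_slice_profile: dict[str, np.ndarray] = {}
    per_volume: dict[str, float] = {}
    vox_a, vox_b = [], []
    for subj in sorted(masks_a):
        a, b = np.asarray(masks_a[subj]), np.asarray(masks_b[subj])
        if a.shape != b.shape:
            raise ValueError(f"mask shapes differ for subject {subj}")
        vals, nonempty = slice_ious(a, b)
        per_slice[subj] = vals.tolist()
        per_slice_profile[subj] = np.where(nonempty, vals, np.nan)
        if volume_metric == "voxel":
            per_volume[subj] = iou_per_volume(a, b)
        else:
            per_volume[subj] = iou_per_volume_slicemean(a, b)
        vox_a.append(int(np.count_nonzero(a)))
        vox_b.append(int(np.count_nonzero(b)))
    all_slice = np.concatenate(
        [v[~np.isnan(v)] for v in per_slice_profile.values()]
    )
    vols = np.array(list(per_volume.values()))
    ba = reg = pt = None
    if len(vols) >= 4 and np.var(vox_a) > 0:
        ba = bland_altman(vox_a, vox_b)
        reg = linreg(vox_a, vox_b)
        pt = paired_compare(vox_a, vox_b)
    return AgreementReport(
        per_slice_iou=per_slice,
        per_volume_iou=per_volume,
        slice_mean=float(all_slice.mean()) if all_slice.size else float("nan"),
        slice_sd=float(all_slice.std(ddof=1)) if all_slice.size > 1 else 0.0,
        volume_mean=float(vols.mean()),
        volume_sd=float(vols.std(ddof=1)) if len(vols) > 1 else 0.0,
        profile=craniocaudal_profile(per_slice_profile, n_bins=n_bins),
        bland_altman_volume=ba,
        regression_volume=reg,
        paired_test_volume=pt,
    )
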