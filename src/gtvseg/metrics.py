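"""Evaluation: Dice similarity coefficient, Hausdorff distance, cohort summaries.

DSC between predicted voxel set A and reference voxel set B is
``2|A∩B| / (|A|+|B|)``.  The Hausdorff distance is the symmetric
``max(h(A,B), h(B,A))`` with ``h(A,B) = max_{a∈A} min_{b∈B} d(a,b)`` over
all mask voxel coordinates; it is reported in mm.  Two mm conversions are
offered:

* ``anisotropic`` (default) — Euclidean distance in physical space, each
  axis scaled by its own voxel spacing;
* ``paper_scalar`` — distance in voxel-index units multiplied by the
  in-plane pixel size, the convention used when anisotropy is ignored.

Directed minima are obtained from an exact Euclidean distance transform of
each mask, so the computation scales with the grid rather than with
|A|x|B|.  Cohort order statistics use the median-of-halves (Tukey hinge)
quartile convention with 1.5 x IQR box-plot outliers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_formats import Mask

__all__ = [
    "CaseMetrics",
    "CohortSummary",
    "dice_coefficient",
    "hausdorff_distance",
    "evaluate_case",
    "evaluate_cohort",
    "summarize_cohort",
    "compare_single_vs_average",
]


@dataclass(frozen=True)
class CaseMetrics:
    case_id: str
    dsc: float
    hd_mm: float | None  # None when the prediction is empty (HD undefined)
    relative_volume_pct: float | None = None


@dataclass(frozen=True)
class CohortSummary:
    n: int
    minimum: float
    q25: float
    median: float
    q75: float
    maximum: float
    mean: float
    p90: float
    outliers: tuple[float, ...] = ()


def _check_geometry(a: Mask, b: Mask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    if a.spacing != b.spacing:
        raise ValueError(f"mask spacings differ: {a.spacing} vs {b.spacing}")


def dice_coefficient(a: Mask, b: Mask) -> float:
    """2|A∩B| / (|A|+|B|) on the whole-case 3D grids; symmetric; in [0,1]."""
    _check_geometry(a, b)
    na, nb = a.voxel_count(), b.voxel_count()
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined: both masks are empty (0/0)")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def _directed_hd(src: Mask, dst: Mask, sampling: Sequence[float]) -> float:
    """max over src voxels of the distance to the nearest dst voxel."""
    dt = ndimage.distance_transform_edt(dst.voxels == 0, sampling=sampling)
    return float(dt[src.voxels.astype(bool)].max())


def hausdorff_distance(
    a: Mask,
    b: Mask,
    spacing: tuple[float, float, float] | None = None,
    mode: str = "anisotropic",
    symmetric: bool = True,
) -> float:
    """Hausdorff distance between two nonempty masks, in mm.

    ``mode='anisotropic'`` measures Euclidean distance in physical
    coordinates; ``mode='paper_scalar'`` measures in voxel indices and
    multiplies by the in-plane pixel size.  ``symmetric=False`` gives the
    directed distance h(A,B) only.
    """
    _check_geometry(a, b)
    if a.voxel_count() == 0 or b.voxel_count() == 0:
        raise ValueError("Hausdorff distance undefined for an empty mask")
    if spacing is None:
        spacing = a.spacing
    if mode == "anisotropic":
        sampling: tuple[float, ...] = tuple(spacing)
        scale = 1.0
    elif mode == "paper_scalar":
        sampling = (1.0, 1.0, 1.0)
        scale = float(spacing[1])  # in-plane pixel size (row == col for square pixels)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    h_ab = _directed_hd(a, b, sampling)
    if not symmetric:
        return h_ab * scale
    h_ba = _directed_hd(b, a, sampling)
    return max(h_ab, h_ba) * scale


def evaluate_case(
    pred: Mask,
    truth: Mask,
    spacing: tuple[float, float, float] | None = None,
    case_id: str = "",
    hd_mode: str = "anisotropic",
) -> CaseMetrics:
    """DSC + HD of one prediction.  An empty prediction scores DSC 0 and a
    flagged, undefined HD (recorded as None with a warning) rather than a
    fabricated distance."""
    _check_geometry(pred, truth)
    if truth.voxel_count() == 0:
        raise ValueError(f"case {case_id!r}: reference mask is empty")
    if pred.voxel_count() == 0:
        warnings.warn(f"case {case_id!r}: empty prediction; HD undefined", stacklevel=2)
        return CaseMetrics(case_id=case_id, dsc=0.0, hd_mm=None)
    return CaseMetrics(
        case_id=case_id,
        dsc=dice_coefficient(pred, truth),
        hd_mm=hausdorff_distance(pred, truth, spacing, mode=hd_mode),
    )


def _area_sum_volume(mask: Mask) -> float:
    """Tumor 'volume' as the sum of per-slice cross-sectional areas (mm^2)."""
    per_slice = mask.voxels.reshape(mask.shape[0], -1).sum(axis=1)
    return float(per_slice.sum() * mask.spacing[1] * mask.spacing[2])


def evaluate_cohort(
    preds: Mapping[str, Mask],
    truths: Mapping[str, Mask],
    hd_mode: str = "anisotropic",
) -> list[CaseMetrics]:
    """Per-case metrics plus relative tumor volume (% of the cohort maximum)."""
    if set(preds) != set(truths):
        raise ValueError("prediction and reference case sets differ")
    volumes = {cid: _area_sum_volume(truths[cid]) for cid in truths}
    vmax = max(volumes.values())
    out = []
    for cid in preds:
        m = evaluate_case(preds[cid], truths[cid], case_id=cid, hd_mode=hd_mode)
        rel = 100.0 * volumes[cid] / vmax if vmax > 0 else None
        out.append(
            CaseMetrics(case_id=cid, dsc=m.dsc, hd_mm=m.hd_mm, relative_volume_pct=rel)
        )
    return out


# ------------------------------------------------------------- summaries


def _hinges(sorted_vals: np.ndarray) -> tuple[float, float]:
    """Tukey hinges: medians of the lower/upper halves (middle value excluded
    when n is odd)."""
    n = sorted_vals.size
    half = n // 2
    lower = sorted_vals[:half]
    upper = sorted_vals[n - half :]
    if half == 0:  # n == 1
        return float(sorted_vals[0]), float(sorted_vals[0])
    return float(np.median(lower)), float(np.median(upper))


def summarize_cohort(values: Sequence[float] | Sequence[CaseMetrics],
                     metric: str = "dsc") -> CohortSummary:
    """Order statistics of one metric over the cohort.

    Accepts raw numbers or :class:`CaseMetrics` (selecting ``metric``);
    ``None`` entries (undefined HD) are dropped.  Outliers follow the
    1.5 x IQR box-plot convention on the Tukey hinges.
    """
    vals: list[float] = []
    for v in values:
        if isinstance(v, CaseMetrics):
            v = getattr(v, metric if metric != "hd" else "hd_mm")
        if v is not None:
            vals.append(float(v))
    if not vals:
        raise ValueError("no values to summarize")
    arr = np.sort(np.asarray(vals, dtype=float))
    q25, q75 = _hinges(arr)
    iqr = q75 - q25
    lo, hi = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    outliers = tuple(float(v) for v in arr if v < lo or v > hi)
    return CohortSummary(
        n=arr.size,
        minimum=float(arr[0]),
        q25=q25,
        median=float(np.median(arr)),
        q75=q75,
        maximum=float(arr[-1]),
        mean=float(arr.mean()),
        p90=float(np.percentile(arr, 90)),
        outliers=outliers,
    )


def compare_single_vs_average(
    member_metrics: Mapping[str, Sequence[CaseMetrics]],
    ensemble_metrics: Sequence[CaseMetrics],
    metric: str = "dsc",
) -> pd.DataFrame:
    """Per-condition cohort summaries: each of the six single models vs the
    model average, over the identical case set.

    Rows: the six members then ``model_average``; columns: the summary
    order statistics plus the outlier count.
    """
    ens_ids = {m.case_id for m in ensemble_metrics}
    for name, ms in member_metrics.items():
        if {m.case_id for m in ms} != ens_ids:
            raise ValueError(f"member {name!r} covers a different case set")
    rows = {}
    for name, ms in list(member_metrics.items()) + [("model_average", list(ensemble_metrics))]:
        s = summarize_cohort(ms, metric=metric)
        rows[name] = {
            "n": s.n, "min": s.minimum, "q25": s.q25, "median": s.median,
            "q75": s.q75, "max": s.maximum, "mean": s.mean, "p90": s.p90,
            "n_outliers": len(s.outliers),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
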