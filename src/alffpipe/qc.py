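"""Subject-level quality control.

Exclusion mirrors common multi-site practice: a subject is dropped when the
signal-fluctuation-to-noise ratio (SFNR) of a central ROI falls below 150, or
when the maximal translation relative to the first frame exceeds 4 mm.  Both
thresholds are strict inequalities and configurable.  Mean framewise
displacement (sum of absolute frame-to-frame parameter changes, rotations
converted to arc length on a 50 mm sphere) is reported but does not enter the
default exclusion rule.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import BoldRun, MotionTrace, SubjectRecord

DEFAULT_SFNR_MIN = 150.0
DEFAULT_MOTION_MAX_MM = 4.0
DEFAULT_ROTATION_RADIUS_MM = 50.0
DEFAULT_ROI_SIDE = 3


@dataclasses.dataclass
class QCResult:
    sfnr: float
    max_abs_translation_mm: float
    mean_fd_mm: float
    passed: bool = True
    reasons: list[str] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        for v in (self.sfnr, self.max_abs_translation_mm, self.mean_fd_mm):
            if not np.isfinite(v):
                raise ValueError("QC summaries must be finite")


def center_roi_mask(brain_mask: np.ndarray, side: int = DEFAULT_ROI_SIDE) -> np.ndarray:
    """Cubic ROI of the given side centred at the brain-mask centroid."""
    if side < 1:
        raise ValueError("ROI side must be >= 1")
    idx = np.argwhere(brain_mask)
    if idx.size == 0:
        raise ValueError("brain mask is empty")
    center = np.round(idx.mean(axis=0)).astype(int)
    roi = np.zeros_like(brain_mask, dtype=bool)
    lo = np.maximum(center - (side - 1) // 2, 0)
    hi = np.minimum(lo + side, brain_mask.shape)
    roi[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return roi


def compute_sfnr(run: BoldRun, roi_side: int = DEFAULT_ROI_SIDE) -> float:
    """Mean signal over mean temporal standard deviation in a central cubic ROI."""
    roi = center_roi_mask(run.brain_mask, roi_side)
    series = run.data[roi]  # (V, t)
    if series.size == 0:
        raise ValueError("ROI is empty")
    sds = series.std(axis=1, ddof=1)
    if np.any(sds == 0):
        raise ValueError("degenerate ROI: constant voxel time series")
    return float(series.mean() / sds.mean())


def max_abs_displacement(trace: MotionTrace) -> float:
    """Max over frames/axes of |translation - translation at frame 1| (mm)."""
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames")
    rel = trace.translations - trace.translations[0]
    return float(np.abs(rel).max())


def mean_framewise_displacement(
    trace: MotionTrace, rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM
) -> float:
    """Mean over frames 2..T of sum|dtrans| + radius * sum|drot|."""
    if trace.n_frames < 2:
        raise ValueError("need at least 2 frames")
    d = np.diff(trace.values, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + rotation_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return float(fd.mean())


def qc_subject(run: BoldRun, trace: MotionTrace, roi_side: int = DEFAULT_ROI_SIDE) -> QCResult:
    return QCResult(
        sfnr=compute_sfnr(run, roi_side),
        max_abs_translation_mm=max_abs_displacement(trace),
        mean_fd_mm=mean_framewise_displacement(trace),
    )


def apply_qc(
    records: list[tuple[SubjectRecord, QCResult]],
    sfnr_min: float = DEFAULT_SFNR_MIN,
    motion_max_mm: float = DEFAULT_MOTION_MAX_MM,
) -> tuple[list[tuple[SubjectRecord, QCResult]], list[tuple[SubjectRecord, QCResult]]]:
    """Partition subjects into (retained, excluded); strict thresholds.

    A subject is excluded iff SFNR < ``sfnr_min`` or maximal translation
    > ``motion_max_mm``.  The partition is order-stable and the input QCResults
    gain their ``passed``/``reasons`` fields.
    """
    retained, excluded = [], []
    for rec, res in records:
        reasons = []
        if res.sfnr < sfnr_min:
            reasons.append(f"SFNR<{sfnr_min:g}")
        if res.max_abs_translation_mm > motion_max_mm:
            reasons.append(f"motion>{motion_max_mm:g}mm")
        res.reasons = reasons
        res.passed = not reasons
        (retained if res.passed else excluded).append((rec, res))
    return retained, excluded


def qc_report(records: list[tuple[SubjectRecord, QCResult]]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": rec.subject_id,
            "site_id": rec.site_id,
            "diagnosis": rec.diagnosis,
            "sfnr": res.sfnr,
            "max_abs_translation_mm": res.max_abs_translation_mm,
            "mean_fd_mm": res.mean_fd_mm,
            "passed": res.passed,
            "reasons": ";".join(res.reasons),
        }
        for rec, res in records
    ]
    return pd.DataFrame(rows)
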