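"""Nuisance regression: orthogonalise voxel time series against confounds.

Each in-brain voxel series is replaced by its residual from an ordinary
least-squares fit on: intercept, linear and quadratic trends (Legendre
polynomials on [-1, 1] for conditioning — the projection space is the same),
the six rigid-body motion parameters, and the mean WM and CSF series (p = 11).
The solve uses pseudoinverse semantics so collinear designs (e.g. a motion
random walk nearly parallel to the linear trend) stay well-defined.

WM/CSF masks come from mean tissue-probability maps thresholded strictly above
0.99 and nearest-neighbour resampled to the functional grid.  Compartment mean
series are taken from the raw (untrended) data; the trends are separate design
columns.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from numpy.polynomial import legendre

from .io import BoldRun, MotionTrace

DEFAULT_TISSUE_THRESHOLD = 0.99


@dataclasses.dataclass
class TissueMasks:
    wm: np.ndarray
    csf: np.ndarray
    threshold: float = DEFAULT_TISSUE_THRESHOLD

    def __post_init__(self) -> None:
        self.wm = np.asarray(self.wm).astype(bool)
        self.csf = np.asarray(self.csf).astype(bool)
        if self.wm.shape != self.csf.shape:
            raise ValueError("WM and CSF masks must share a grid")
        if np.any(self.wm & self.csf):
            raise ValueError("WM and CSF masks overlap")


@dataclasses.dataclass
class NuisanceDesign:
    """t x p design matrix with named columns."""

    matrix: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.columns):
            raise ValueError("design matrix / column-name mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("design matrix contains non-finite values")


def nearest_neighbor_resample(volume: np.ndarray, target_shape) -> np.ndarray:
    """Resample by the voxel-centre rule: source index = round((i+0.5)*ns/nt - 0.5)."""
    volume = np.asarray(volume)
    idx = []
    for nt, ns in zip(target_shape, volume.shape):
        src = np.round((np.arange(nt) + 0.5) * ns / nt - 0.5).astype(int)
        idx.append(np.clip(src, 0, ns - 1))
    return volume[np.ix_(*idx)]


def build_tissue_masks(
    mean_wm_prob: np.ndarray,
    mean_csf_prob: np.ndarray,
    target_shape,
    threshold: float = DEFAULT_TISSUE_THRESHOLD,
) -> TissueMasks:
    """Binarise probability maps at strictly > threshold, then NN-resample."""
    masks = {}
    for name, prob in (("WM", mean_wm_prob), ("CSF", mean_csf_prob)):
        prob = np.asarray(prob, dtype=np.float64)
        if prob.min() < 0 or prob.max() > 1:
            raise ValueError(f"{name} probability map outside [0, 1]")
        binary = prob > threshold
        if not binary.any():
            raise ValueError(f"{name} mask empty after thresholding at {threshold}")
        resampled = nearest_neighbor_resample(binary, target_shape)
        if not resampled.any():
            raise ValueError(f"{name} mask empty after resampling to {tuple(target_shape)}")
        masks[name] = resampled
    overlap = masks["WM"] & masks["CSF"]
    if overlap.any():
        raise ValueError("WM and CSF masks overlap after thresholding")
    return TissueMasks(wm=masks["WM"], csf=masks["CSF"], threshold=threshold)


def mean_compartment_series(run: BoldRun, mask: np.ndarray) -> np.ndarray:
    """Frame-wise arithmetic mean over mask voxels."""
    mask = np.asarray(mask).astype(bool)
    if mask.shape != run.spatial_shape:
        raise ValueError("compartment mask is not on the run grid")
    if not mask.any():
        raise ValueError("compartment mask is empty")
    return run.data[mask].mean(axis=0)


def trend_columns(n_frames: int) -> np.ndarray:
    """Intercept, linear and quadratic Legendre polynomials on [-1, 1]."""
    x = np.linspace(-1.0, 1.0, n_frames)
    return legendre.legvander(x, 2)


def build_design(run: BoldRun, trace: MotionTrace, masks: TissueMasks) -> NuisanceDesign:
    if trace.n_frames != run.n_frames:
        raise ValueError(
            f"motion trace has {trace.n_frames} frames, run has {run.n_frames}"
        )
    cols = [trend_columns(run.n_frames), trace.values]
    names = ["intercept", "trend_linear", "trend_quadratic"] + [
        f"motion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")
    ]
    cols.append(mean_compartment_series(run, masks.wm)[:, None])
    names.append("wm_mean")
    cols.append(mean_compartment_series(run, masks.csf)[:, None])
    names.append("csf_mean")
    return NuisanceDesign(matrix=np.hstack(cols), columns=names)


def regress_design(data_2d: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """Residuals of each row of (V, t) data against the design's column space.

    Columns are unit-normalised for conditioning, and columns that are
    numerically zero (e.g. the compartment mean of an already-residualised
    run) are dropped: their direction is floating-point noise, not signal.
    """
    X = design.matrix
    norms = np.linalg.norm(X, axis=0)
    keep = norms > 1e-8 * max(norms.max(), 1e-300)
    Xn = X[:, keep] / norms[keep]
    beta, *_ = np.linalg.lstsq(Xn, data_2d.T, rcond=None)
    return data_2d - (Xn @ beta).T


def regress_nuisance(run: BoldRun, trace: MotionTrace, masks: TissueMasks) -> BoldRun:
    """Return a run whose in-brain voxels are OLS residuals; out-of-brain zeroed."""
    design = build_design(run, trace, masks)
    data = np.zeros_like(run.data)
    data[run.brain_mask] = regress_design(run.data[run.brain_mask], design)
    return dataclasses.replace(run, data=data)
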