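"""Reading and writing the formats the pipeline touches.

Volumes are NIfTI-1 (.nii / .nii.gz) via nibabel; motion traces are plain-text
six-column files (translations in mm, then rotations in radians — the
realignment-parameter convention); subject tables are tab-separated. Voxel
indices are 0-based and no world-coordinate logic is applied: the synthetic
phantom lives on its own grid.
"""
from __future__ import annotations

import dataclasses
import logging
import time
from contextlib import contextmanager
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("alffpipe")

DIAGNOSES = ("HC", "SZ")

SUBJECT_TABLE_COLUMNS = [
    "subject_id",
    "site_id",
    "diagnosis",
    "age_years",
    "sex",
    "run_path",
    "motion_path",
    "wm_prob_path",
    "csf_prob_path",
    "mask_path",
]


@dataclasses.dataclass
class BoldRun:
    """One subject's 4D BOLD time series plus acquisition metadata.

    ``data`` is (x, y, z, t) in arbitrary scanner units; ``brain_mask`` is a
    boolean volume on the same spatial grid; ``voxel_sizes_mm`` is kept so
    spatial smoothing can convert an FWHM in mm to voxels.
    """

    data: np.ndarray
    tr_seconds: float
    brain_mask: np.ndarray
    subject_id: str = ""
    site_id: str = ""
    diagnosis: str = "HC"
    age_years: float = 0.0
    voxel_sizes_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("not a 4D series")
        if self.data.shape[3] < 8:
            raise ValueError(
                f"time dimension must be >= 8 frames, got {self.data.shape[3]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be > 0, got {self.tr_seconds}")
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"brain mask shape {self.brain_mask.shape} does not match "
                f"data spatial shape {self.data.shape[:3]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclasses.dataclass
class MotionTrace:
    """Per-frame rigid-body parameters: t x 6, translations (mm) then rotations (rad)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError(
                f"motion trace must be t x 6, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("motion trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]


@dataclasses.dataclass
class SubjectRecord:
    """One row of the cohort table: identity, covariates, and file locations."""

    subject_id: str
    site_id: str
    diagnosis: str
    age_years: float
    sex: str = "U"
    run_path: str = ""
    motion_path: str = ""
    wm_prob_path: str = ""
    csf_prob_path: str = ""
    mask_path: str = ""

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"diagnosis must be one of {DIAGNOSES}, got {self.diagnosis!r}")


def _affine(voxel_sizes_mm) -> np.ndarray:
    aff = np.diag(list(voxel_sizes_mm) + [1.0]).astype(float)
    return aff


def read_bold(
    path,
    tr_override: float | None = None,
    mask_path=None,
    subject_id: str = "",
    site_id: str = "",
    diagnosis: str = "HC",
    age_years: float = 0.0,
) -> BoldRun:
    """Load a 4D NIfTI run.

    TR is taken from the header's fourth zoom; a non-positive header TR must be
    overridden via ``tr_override`` or loading fails.  When ``mask_path`` is not
    given the brain mask is all-true.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError("not a 4D series")
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    tr = float(tr_override) if tr_override is not None else float(zooms[3])
    if tr <= 0:
        raise ValueError(f"header TR {zooms[3]} invalid and no override given")
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0.5
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldRun(
        data=data,
        tr_seconds=tr,
        brain_mask=mask,
        subject_id=subject_id,
        site_id=site_id,
        diagnosis=diagnosis,
        age_years=age_years,
        voxel_sizes_mm=tuple(float(z) for z in zooms[:3]),
    )


def write_bold(run: BoldRun, path) -> None:
    """Write a BoldRun as NIfTI-1 with the TR in the header's fourth zoom."""
    img = nib.Nifti1Image(
        run.data.astype(np.float64), _affine(run.voxel_sizes_mm)
    )
    img.header.set_zooms(tuple(run.voxel_sizes_mm) + (run.tr_seconds,))
    nib.save(img, str(path))


def read_motion_trace(path, n_frames: int) -> MotionTrace:
    """Read a six-column whitespace-separated motion-parameter file."""
    try:
        values = np.loadtxt(str(path), dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric token in motion file {path}: {exc}") from exc
    if values.shape[1] != 6:
        raise ValueError(
            f"motion file {path} has {values.shape[1]} columns, expected 6"
        )
    if values.shape[0] != n_frames:
        raise ValueError(
            f"motion file {path} has {values.shape[0]} rows, expected {n_frames}"
        )
    return MotionTrace(values=values)


def write_motion_trace(trace: MotionTrace, path) -> None:
    np.savetxt(str(path), trace.values, fmt="%.10g")


def write_volume(
    values: np.ndarray,
    path,
    voxel_sizes_mm=(3.0, 3.0, 3.0),
    mask: np.ndarray | None = None,
    fill: float = 0.0,
) -> None:
    """Write a 3D volume.

    Non-finite values are only tolerated outside ``mask`` and are replaced by
    ``fill``; in-mask non-finite values raise.  Out-of-mask voxels are always
    written as ``fill`` so downstream viewers never see NaNs.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3:
        raise ValueError(f"expected 3D volume, got ndim={values.ndim}")
    if mask is None:
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values and no mask was given")
        out = values
    else:
        mask = np.asarray(mask).astype(bool)
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("volume contains non-finite values inside the mask")
        out = np.full_like(values, fill)
        out[mask] = values[mask]
    nib.save(nib.Nifti1Image(out, _affine(voxel_sizes_mm)), str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D volume, got ndim={img.ndim}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), zooms


def read_subject_table(path) -> pd.DataFrame:
    table = pd.read_csv(str(path), sep="\t", dtype={"subject_id": str, "site_id": str})
    missing = [c for c in ("subject_id", "site_id", "diagnosis", "age_years") if c not in table]
    if missing:
        raise ValueError(f"subject table missing columns: {missing}")
    bad = set(table["diagnosis"]) - set(DIAGNOSES)
    if bad:
        raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
    return table


def write_subject_table(table: pd.DataFrame, path) -> None:
    table.to_csv(str(path), sep="\t", index=False)


def load_config(path) -> dict:
    with open(str(path)) as fh:
        cfg = yaml.safe_load(fh)
    return cfg if cfg is not None else {}


@contextmanager
def stage(name: str, subject: str = "") -> Iterator[None]:
    """Structured log line with stage, subject, and elapsed time."""
    t0 = time.perf_counter()
    yield
    log.info("stage=%s subject=%s elapsed=%.3fs", name, subject, time.perf_counter() - t0)
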