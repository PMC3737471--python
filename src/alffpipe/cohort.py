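"""Synthetic multi-site case–control BOLD cohorts with known ground truth.

The phantom is a small ellipsoidal "brain" on its own grid (default 16x16x12
voxels of 3 mm, 162 frames at TR 2 s) with nested CSF / WM / GM compartments.
Each voxel's series is

    offset_site + gain_site * g(v) * [ alpha(v, group) * s_low(t)
                                       + beta(v) * s_phys(t)
                                       + gamma(v) * m(t) + eps(t) ]

* ``s_low`` — unit-variance band-limited (0.01–0.08 Hz) noise built in the
  frequency domain on exact DFT bins (flat magnitude, random phases), so band
  membership is exact and per-bin amplitude is deterministic.
* ``alpha`` — low-band amplitude: the group effect.  For an HC gray-matter
  voxel it is the low-band sd; for an SZ voxel inside an effect region it is
  multiplied by the region's amplitude ratio r = SZ/HC.
* ``s_phys`` — respiratory + cardiac sinusoids defined in continuous time and
  sampled every TR, so aliasing emerges from the sampling itself (0.3 Hz
  respiration aliases to 0.20 Hz at TR 2 s; 1.03 Hz cardiac aliases to
  0.03 Hz, inside the low band).  ``beta`` loads them strongly on WM/CSF and
  weakly on GM.
* ``gamma * m`` — the x-translation motion trace coupled through a left–right
  spatial gradient.
* ``g(v)`` — a multiplicative distortion bump in the anterior/inferior brain
  for the one "vendor outlier" site, emulating B0-related regional effects.

Everything is deterministic under the master seed; per-subject seeds follow
the counter scheme ``SeedSequence((master_seed, subject_index))`` with the
subject index running over sites in order, HC before SZ.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (
    BoldRun,
    MotionTrace,
    SubjectRecord,
    write_bold,
    write_motion_trace,
    write_subject_table,
    write_volume,
)
from .spectral import band_mask

DEFAULT_SHAPE = (16, 16, 12)
DEFAULT_N_FRAMES = 162
DEFAULT_TR = 2.0
DEFAULT_VOXEL_MM = (3.0, 3.0, 3.0)


@dataclasses.dataclass
class SiteSpec:
    site_id: str
    n_hc: int
    n_sz: int
    intensity_gain: float = 1.0
    intensity_offset: float = 0.0
    vendor_flag: bool = False
    age_mean: float = 38.0
    age_sd: float = 11.0

    def __post_init__(self) -> None:
        if self.n_hc < 0 or self.n_sz < 0:
            raise ValueError("group sizes must be >= 0")


@dataclasses.dataclass
class EffectRegion:
    """Axis-aligned box of GM voxels with group amplitude ratio r = SZ/HC."""

    name: str
    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("amplitude ratio must be > 0")

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.box
        m[x0:x1, y0:y1, z0:z1] = True
        return m


@dataclasses.dataclass
class CohortSpec:
    """Full description of a synthetic cohort; fixing ``master_seed`` fixes output."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    n_frames: int = DEFAULT_N_FRAMES
    tr_seconds: float = DEFAULT_TR
    voxel_sizes_mm: tuple[float, float, float] = DEFAULT_VOXEL_MM
    sites: list[SiteSpec] = dataclasses.field(default_factory=list)
    regions: list[EffectRegion] = dataclasses.field(default_factory=list)
    band_hz: tuple[float, float] = (0.01, 0.08)
    base_intensity: float = 1000.0
    low_band_sd: float = 3.0
    low_band_wmcsf_frac: float = 0.3
    white_noise_sd: float = 3.0
    resp_freq_hz: float = 0.3
    resp_amp: float = 1.0
    # 1 + 10/324 Hz: at TR 2 s and 162 frames this aliases onto DFT bin 10
    # (0.0309 Hz), squarely inside the low band — the channel through which
    # nuisance regression lowers fALFF.
    cardiac_freq_hz: float = 1.0 + 10.0 / 324.0
    cardiac_amp: float = 6.0
    phys_gm_frac: float = 0.5
    motion_step_sd_mm: float = 0.02
    motion_rot_frac: float = 0.01
    motion_coupling: float = 2.0
    vendor_distortion_amp: float = 0.3
    qc_mover_fraction: float = 0.0
    qc_mover_step_multiplier: float = 25.0
    qc_noisy_fraction: float = 0.0
    qc_noisy_white_multiplier: float = 3.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 8:
            raise ValueError("need at least 8 frames")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        for f in (self.resp_freq_hz, self.cardiac_freq_hz):
            if f <= 0:
                raise ValueError("physiological frequencies must be > 0")
        masks = phantom_masks(self.shape)
        for region in self.regions:
            rm = region.mask(self.shape)
            if not rm.any():
                raise ValueError(f"effect region {region.name!r} is empty")
            if np.any(rm & ~masks["gm"]):
                raise ValueError(
                    f"effect region {region.name!r} extends outside GM labels"
                )

    @property
    def n_subjects(self) -> int:
        return sum(s.n_hc + s.n_sz for s in self.sites)


@dataclasses.dataclass
class CohortTruth:
    """Ledger of injected effects, sufficient to score recovery."""

    region_ratios: dict[str, float]
    region_sizes: dict[str, int]
    theoretical_d: dict[str, float]
    site_params: pd.DataFrame
    subjects: pd.DataFrame


# --------------------------------------------------------------------------
# Phantom geometry


def phantom_masks(shape) -> dict[str, np.ndarray]:
    """Ellipsoidal brain with a central CSF box, a WM shell, and a GM remainder."""
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    rx, ry, rz = nx / 2 - 0.5, ny / 2 - 0.5, nz / 2 - 0.5
    brain = (
        ((ix - cx) / rx) ** 2 + ((iy - cy) / ry) ** 2 + ((iz - cz) / rz) ** 2
    ) <= 1.0

    def box(fx, fy, fz):
        m = np.zeros(shape, dtype=bool)
        m[
            int(round(cx + fx[0])):int(round(cx + fx[1])),
            int(round(cy + fy[0])):int(round(cy + fy[1])),
            int(round(cz + fz[0])):int(round(cz + fz[1])),
        ] = True
        return m

    csf = box((-2, 2), (-2, 2), (-2, 2)) & brain
    wm = box((-4, 4), (-4, 4), (-4, 4)) & brain & ~csf
    gm = brain & ~wm & ~csf
    return {"brain": brain, "gm": gm, "wm": wm, "csf": csf}


def default_effect_regions(
    shape=DEFAULT_SHAPE, posterior_ratio: float = 1.0, anterior_ratio: float = 1.0
) -> list[EffectRegion]:
    """Posterior (low y) and anterior (high y) GM boxes, ~54 voxels each."""
    nx, ny, nz = shape
    cx, cz = nx // 2, nz // 2
    xs = (cx - 3, cx + 3)
    zs = (cz - 1, cz + 2)
    return [
        EffectRegion("posterior", (xs, (1, 4), zs), posterior_ratio),
        EffectRegion("anterior", (xs, (ny - 4, ny - 1), zs), anterior_ratio),
    ]


def tissue_probability_maps(
    shape, upsample: int = 2, sigma_fine: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """WM/CSF probability maps: smoothed indicators on an upsampled grid.

    Emulates structural-resolution mean segmentations; interiors stay above
    0.99 while edges roll off, so the conservative-threshold path is
    genuinely exercised, as is nearest-neighbour downsampling.
    """
    masks = phantom_masks(shape)
    out = []
    for key in ("wm", "csf"):
        fine = np.repeat(
            np.repeat(np.repeat(masks[key], upsample, 0), upsample, 1), upsample, 2
        ).astype(np.float64)
        out.append(np.clip(ndimage.gaussian_filter(fine, sigma_fine), 0.0, 1.0))
    return out[0], out[1]


# --------------------------------------------------------------------------
# Signal components


def generate_motion(
    n_frames: int, step_sd: float, seed, rot_step_sd: float | None = None
) -> MotionTrace:
    """Cumulative random-walk motion trace; the first row is exactly zero."""
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    rng = np.random.default_rng(seed)
    sds = np.array([step_sd] * 3 + [step_sd if rot_step_sd is None else rot_step_sd] * 3)
    steps = rng.standard_normal((n_frames - 1, 6)) * sds
    values = np.vstack([np.zeros(6), np.cumsum(steps, axis=0)])
    return MotionTrace(values=values)


def band_limited_noise(
    n_voxels: int, n_frames: int, tr_seconds: float, band_hz, rng
) -> np.ndarray:
    """Unit-variance band-limited noise per voxel: flat in-band DFT magnitude,
    uniform random phases, zero outside the band (DC and Nyquist excluded)."""
    freqs = np.fft.rfftfreq(n_frames, d=tr_seconds)
    sel = band_mask(freqs, *band_hz)
    sel[0] = False
    if n_frames % 2 == 0:
        sel[-1] = False
    n_band = int(sel.sum())
    if n_band == 0:
        raise ValueError(f"no DFT bins inside band {band_hz} at N={n_frames}, TR={tr_seconds}")
    mag = n_frames / np.sqrt(2.0 * n_band)  # exact unit variance by Parseval
    spec = np.zeros((n_voxels, len(freqs)), dtype=np.complex128)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_voxels, n_band))
    spec[:, sel] = mag * np.exp(1j * phases)
    return np.fft.irfft(spec, n=n_frames, axis=1)


def physiological_series(spec: CohortSpec, rng) -> np.ndarray:
    """Respiratory + cardiac sinusoids sampled at t*TR (aliasing emerges naturally)."""
    t = np.arange(spec.n_frames) * spec.tr_seconds
    phi_r, phi_c = rng.uniform(0.0, 2.0 * np.pi, size=2)
    return spec.resp_amp * np.sin(2 * np.pi * spec.resp_freq_hz * t + phi_r) + (
        spec.cardiac_amp * np.sin(2 * np.pi * spec.cardiac_freq_hz * t + phi_c)
    )


def _coupling_gradient(shape, brain: np.ndarray, gain: float) -> np.ndarray:
    """Left–right linear gradient in [-gain, gain], zero at the grid centre."""
    nx = shape[0]
    grad = (np.arange(nx) - (nx - 1) / 2) / ((nx - 1) / 2)
    return gain * grad[:, None, None] * np.ones(shape) * brain


def _distortion_field(shape, brain: np.ndarray, amp: float) -> np.ndarray:
    """1 + Gaussian bump at the anterior/inferior brain (B0-like regional gain)."""
    nx, ny, nz = shape
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    focus = ((nx - 1) / 2, ny - 3.0, 2.0)
    d2 = (ix - focus[0]) ** 2 + (iy - focus[1]) ** 2 + (iz - focus[2]) ** 2
    return (1.0 + amp * np.exp(-d2 / (2.0 * 3.0**2))) * brain


# --------------------------------------------------------------------------
# Subject- and cohort-level generation


@dataclasses.dataclass
class SubjectAssignment:
    subject_id: str
    site: SiteSpec
    diagnosis: str
    age_years: float
    sex: str = "U"
    motion_multiplier: float = 1.0
    white_multiplier: float = 1.0


def generate_subject_run(
    spec: CohortSpec, assignment: SubjectAssignment, seed
) -> tuple[BoldRun, MotionTrace]:
    """One subject's 4D run and motion trace under the cohort's noise model."""
    rng = np.random.default_rng(seed)
    masks = phantom_masks(spec.shape)
    brain = masks["brain"]
    n_vox = int(brain.sum())
    site = assignment.site

    # per-voxel low-band amplitude
    alpha = np.where(
        masks["gm"], spec.low_band_sd, spec.low_band_sd * spec.low_band_wmcsf_frac
    )
    if assignment.diagnosis == "SZ":
        for region in spec.regions:
            alpha = np.where(region.mask(spec.shape), alpha * region.ratio, alpha)

    beta = np.where(masks["gm"], spec.phys_gm_frac, 1.0)
    gamma = _coupling_gradient(spec.shape, brain, spec.motion_coupling)

    trace = generate_motion(
        spec.n_frames,
        spec.motion_step_sd_mm * assignment.motion_multiplier,
        rng,
        rot_step_sd=spec.motion_step_sd_mm
        * spec.motion_rot_frac
        * assignment.motion_multiplier,
    )
    s_low = band_limited_noise(n_vox, spec.n_frames, spec.tr_seconds, spec.band_hz, rng)
    s_phys = physiological_series(spec, rng)
    eps = rng.standard_normal((n_vox, spec.n_frames)) * (
        spec.white_noise_sd * assignment.white_multiplier
    )

    fluct = (
        alpha[brain][:, None] * s_low
        + beta[brain][:, None] * s_phys[None, :]
        + gamma[brain][:, None] * trace.values[:, 0][None, :]
        + eps
    )
    if site.vendor_flag and spec.vendor_distortion_amp > 0:
        fluct *= _distortion_field(spec.shape, brain, spec.vendor_distortion_amp)[
            brain
        ][:, None]

    offset = spec.base_intensity + site.intensity_offset
    data = np.zeros(spec.shape + (spec.n_frames,))
    data[brain] = offset + site.intensity_gain * fluct

    run = BoldRun(
        data=data,
        tr_seconds=spec.tr_seconds,
        brain_mask=brain,
        subject_id=assignment.subject_id,
        site_id=site.site_id,
        diagnosis=assignment.diagnosis,
        age_years=assignment.age_years,
        voxel_sizes_mm=spec.voxel_sizes_mm,
    )
    return run, trace


def subject_assignments(spec: CohortSpec) -> list[SubjectAssignment]:
    """Deterministic subject roster: sites in order, HC before SZ."""
    if spec.n_subjects == 0:
        raise ValueError("cohort spec contains zero subjects")
    roster = []
    index = 0
    for site in spec.sites:
        for diagnosis, count in (("HC", site.n_hc), ("SZ", site.n_sz)):
            for _ in range(count):
                rng = np.random.default_rng(
                    np.random.SeedSequence((spec.master_seed, index))
                )
                age = float(np.clip(rng.normal(site.age_mean, site.age_sd), 18.0, 65.0))
                sex = "M" if rng.random() < 0.65 else "F"
                motion_mult = 1.0
                if rng.random() < spec.qc_mover_fraction:
                    motion_mult = spec.qc_mover_step_multiplier
                white_mult = 1.0
                if rng.random() < spec.qc_noisy_fraction:
                    white_mult = spec.qc_noisy_white_multiplier
                roster.append(
                    SubjectAssignment(
                        subject_id=f"sub{index:04d}",
                        site=site,
                        diagnosis=diagnosis,
                        age_years=age,
                        sex=sex,
                        motion_multiplier=motion_mult,
                        white_multiplier=white_mult,
                    )
                )
                index += 1
    return roster


def iter_cohort(spec: CohortSpec):
    """Yield (SubjectRecord, BoldRun, MotionTrace) per subject, deterministically."""
    for index, assignment in enumerate(subject_assignments(spec)):
        run, trace = generate_subject_run(
            spec, assignment, np.random.SeedSequence((spec.master_seed, 1000000 + index))
        )
        record = SubjectRecord(
            subject_id=assignment.subject_id,
            site_id=assignment.site.site_id,
            diagnosis=assignment.diagnosis,
            age_years=assignment.age_years,
            sex=assignment.sex,
        )
        yield record, run, trace


def cohort_truth(spec: CohortSpec, n_mc: int = 2000) -> CohortTruth:
    """Truth ledger: injected ratios, site parameters, theoretical Cohen's d."""
    ratios = {r.name: r.ratio for r in spec.regions}
    sizes = {r.name: int(r.mask(spec.shape).sum()) for r in spec.regions}
    theo = {
        r.name: theoretical_voxel_d(spec, r.ratio, n_mc=n_mc, seed=spec.master_seed)
        for r in spec.regions
    }
    site_params = pd.DataFrame(
        [
            {
                "site_id": s.site_id,
                "n_hc": s.n_hc,
                "n_sz": s.n_sz,
                "intensity_gain": s.intensity_gain,
                "intensity_offset": s.intensity_offset,
                "vendor_flag": s.vendor_flag,
            }
            for s in spec.sites
        ]
    )
    subjects = pd.DataFrame(
        [
            {
                "subject_id": a.subject_id,
                "site_id": a.site.site_id,
                "diagnosis": a.diagnosis,
                "age_years": a.age_years,
                "sex": a.sex,
                "motion_multiplier": a.motion_multiplier,
                "white_multiplier": a.white_multiplier,
            }
            for a in subject_assignments(spec)
        ]
    )
    return CohortTruth(
        region_ratios=ratios,
        region_sizes=sizes,
        theoretical_d=theo,
        site_params=site_params,
        subjects=subjects,
    )


def generate_cohort(spec: CohortSpec, out_dir) -> tuple[pd.DataFrame, CohortTruth]:
    """Write one run + motion file per subject, shared tissue maps, the subject
    table, and the truth ledger (TSV + JSON). Deterministic under the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    wm_prob, csf_prob = tissue_probability_maps(spec.shape)
    fine_vox = tuple(v / 2 for v in spec.voxel_sizes_mm)
    write_volume(wm_prob, out / "mean_wm_prob.nii.gz", voxel_sizes_mm=fine_vox)
    write_volume(csf_prob, out / "mean_csf_prob.nii.gz", voxel_sizes_mm=fine_vox)
    brain = phantom_masks(spec.shape)["brain"]
    write_volume(
        brain.astype(float), out / "brain_mask.nii.gz", voxel_sizes_mm=spec.voxel_sizes_mm
    )

    rows = []
    for record, run, trace in iter_cohort(spec):
        run_path = out / f"{record.subject_id}_bold.nii.gz"
        mot_path = out / f"{record.subject_id}_motion.txt"
        write_bold(run, run_path)
        write_motion_trace(trace, mot_path)
        rows.append(
            {
                "subject_id": record.subject_id,
                "site_id": record.site_id,
                "diagnosis": record.diagnosis,
                "age_years": record.age_years,
                "sex": record.sex,
                "run_path": run_path.name,
                "motion_path": mot_path.name,
                "wm_prob_path": "mean_wm_prob.nii.gz",
                "csf_prob_path": "mean_csf_prob.nii.gz",
                "mask_path": "brain_mask.nii.gz",
            }
        )
    table = pd.DataFrame(rows)
    write_subject_table(table, out / "subjects.tsv")

    truth = cohort_truth(spec)
    truth.site_params.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    truth.subjects.to_csv(out / "truth_subjects.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "region_ratios": truth.region_ratios,
                "region_sizes": truth.region_sizes,
                "theoretical_d": truth.theoretical_d,
                "master_seed": spec.master_seed,
            },
            fh,
            indent=2,
        )
    return table, truth


# --------------------------------------------------------------------------
# Effect-size calibration


def _voxel_amplitude_samples(
    spec: CohortSpec, alpha: float, gamma: float, n_mc: int, rng
) -> np.ndarray:
    """Band amplitude A of n_mc independent virtual subjects at one GM voxel."""
    from .spectral import _one_sided_amplitudes, linear_detrend  # local import, no cycle

    series = alpha * band_limited_noise(
        n_mc, spec.n_frames, spec.tr_seconds, spec.band_hz, rng
    )
    t = np.arange(spec.n_frames) * spec.tr_seconds
    phases = rng.uniform(0, 2 * np.pi, size=(n_mc, 2))
    series += spec.phys_gm_frac * (
        spec.resp_amp * np.sin(2 * np.pi * spec.resp_freq_hz * t + phases[:, :1])
        + spec.cardiac_amp * np.sin(2 * np.pi * spec.cardiac_freq_hz * t + phases[:, 1:])
    )
    if gamma != 0:
        walks = np.cumsum(
            rng.standard_normal((n_mc, spec.n_frames)) * spec.motion_step_sd_mm, axis=1
        )
        walks[:, 0] = 0.0
        series += gamma * walks
    series += rng.standard_normal((n_mc, spec.n_frames)) * spec.white_noise_sd

    amps = _one_sided_amplitudes(linear_detrend(series))
    freqs = np.fft.rfftfreq(spec.n_frames, d=spec.tr_seconds)
    sel = band_mask(freqs, *spec.band_hz)
    return amps[:, sel].mean(axis=1)


def theoretical_voxel_d(
    spec: CohortSpec, ratio: float, gamma: float = 0.0, n_mc: int = 2000, seed=0
) -> float:
    """Population Cohen's d (SZ−HC) implied by an amplitude ratio at a GM voxel.

    Monte-Carlo over virtual subjects under the cohort's full single-voxel
    noise model (subject-mean ALFF normalisation neglected — it is a shared
    scale with negligible between-subject variance).
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 77)))
    a_hc = _voxel_amplitude_samples(spec, spec.low_band_sd, gamma, n_mc, rng)
    a_sz = _voxel_amplitude_samples(spec, spec.low_band_sd * ratio, gamma, n_mc, rng)
    pooled = np.sqrt((a_hc.var(ddof=1) + a_sz.var(ddof=1)) / 2.0)
    return float((a_sz.mean() - a_hc.mean()) / pooled)


def calibrate_ratio(
    spec: CohortSpec, d_target: float, n_mc: int = 4000, seed=0
) -> float:
    """Amplitude ratio r whose implied voxel-level d equals ``d_target``.

    d is linear in (r - 1) to excellent approximation (the amplitude mean is
    linear in r; the sd is noise-dominated), so one probe simulation at
    r = 1.1 fixes the slope and the target inverts in closed form.
    """
    slope = theoretical_voxel_d(spec, 1.1, n_mc=n_mc, seed=seed) / 0.1
    return 1.0 + d_target / slope


# --------------------------------------------------------------------------
# Stock cohort specifications (the package's study conditions)


def table1_sites() -> list[SiteSpec]:
    """Seven sites with the group sizes and ages of the motivating multi-site
    study; site s1 is the outlier-vendor scanner, s7 the implicit baseline."""
    rows = [
        ("s1", 27, 22, 1.15, 300.0, True, 34.4),
        ("s2", 9, 9, 0.97, -50.0, False, 40.2),
        ("s3", 27, 24, 1.03, 40.0, False, 43.6),
        ("s4", 28, 23, 0.99, -20.0, False, 35.3),
        ("s5", 14, 13, 1.01, 10.0, False, 36.5),
        ("s6", 28, 29, 0.95, -30.0, False, 35.4),
        ("s7", 27, 26, 1.00, 0.0, False, 37.6),
    ]
    return [
        SiteSpec(sid, hc, sz, gain, off, vendor, age_mean=age)
        for sid, hc, sz, gain, off, vendor, age in rows
    ]


def headline_spec(master_seed: int = 0) -> CohortSpec:
    """The full 306-subject, 7-site cohort with QC-failing movers/noisy scans
    and bidirectional effect regions (posterior HC>SZ, anterior SZ>HC)."""
    return CohortSpec(
        sites=table1_sites(),
        regions=default_effect_regions(
            posterior_ratio=0.93, anterior_ratio=1.07
        ),
        qc_mover_fraction=0.12,
        qc_noisy_fraction=0.06,
        master_seed=master_seed,
    )


def study_sites(
    n_sites: int = 4, n_per_group: int = 20, vendor_outlier: bool = True
) -> list[SiteSpec]:
    gains = [1.15, 0.97, 1.03, 0.99, 1.01, 0.95, 1.0]
    offsets = [300.0, -50.0, 40.0, -20.0, 10.0, -30.0, 0.0]
    sites = []
    for i in range(n_sites):
        sites.append(
            SiteSpec(
                f"s{i + 1}",
                n_per_group,
                n_per_group,
                intensity_gain=gains[i % len(gains)],
                intensity_offset=offsets[i % len(offsets)],
                vendor_flag=vendor_outlier and i == 0,
            )
        )
    return sites


def null_spec(n_sites: int = 2, n_per_group: int = 15, master_seed: int = 0) -> CohortSpec:
    """No injected group effect anywhere (r = 1): type-I-error conditions."""
    return CohortSpec(
        sites=study_sites(n_sites, n_per_group),
        regions=[],
        master_seed=master_seed,
    )


def recovery_spec(
    d_target: float = 0.8,
    n_sites: int = 4,
    n_per_group: int = 20,
    master_seed: int = 0,
) -> CohortSpec:
    """Posterior HC>SZ and anterior SZ>HC regions at a calibrated |d|."""
    base = CohortSpec(sites=study_sites(n_sites, n_per_group), master_seed=master_seed)
    r = calibrate_ratio(base, d_target, seed=1234)
    return dataclasses.replace(
        base,
        regions=default_effect_regions(
            posterior_ratio=2.0 - r,  # ratio < 1: HC larger
            anterior_ratio=r,
        ),
    )


def megameta_spec(
    d_target: float = 0.8,
    n_sites: int = 4,
    n_per_group: int = 20,
    master_seed: int = 0,
) -> CohortSpec:
    """Homogeneous anterior SZ>HC effect, no site x effect interaction
    (vendor distortion off), for the mega- vs. meta-analysis comparison."""
    base = CohortSpec(
        sites=study_sites(n_sites, n_per_group, vendor_outlier=False),
        vendor_distortion_amp=0.0,
        master_seed=master_seed,
    )
    r = calibrate_ratio(base, d_target, seed=1234)
    return dataclasses.replace(
        base, regions=default_effect_regions(anterior_ratio=r)
    )
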