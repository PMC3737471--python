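"""Voxel-wise low-frequency amplitude maps (ALFF and fALFF).

The per-voxel statistic is the mean one-sided spectral amplitude over the
0.01–0.08 Hz band of the linearly detrended time series,

    A_i = (1/B) * sum_{f_lo <= f_k <= f_hi} a_k,      a_k = c_k |X_k| / N,

with c_k = 2 except at DC and (for even N) Nyquist, so a pure cosine of
amplitude A at an exact DFT bin yields a_k = A.  The subject-level ALFF map is
A_i normalised by the mean of A over in-brain voxels (in-brain mean exactly 1);
fALFF is the ratio of the summed band amplitudes to the summed amplitudes over
all non-DC frequencies, hence lies in [0, 1].

Only a linear trend is removed before the FFT; quadratic detrending belongs to
the separate nuisance-regression path, never here.  Maps are smoothed (8 mm
FWHM by default) after computation, never the time series.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage

from .io import BoldRun

log = logging.getLogger("alffpipe")

DEFAULT_BAND = (0.01, 0.08)
_FREQ_TOL = 1e-12  # absolute slack when testing DFT bin membership in the band


@dataclasses.dataclass
class AmplitudeSpectrum:
    """One-sided amplitude spectrum on exact DFT bins: f_k = k/(N*TR), k=0..N//2."""

    freqs: np.ndarray
    amplitudes: np.ndarray

    @property
    def nyquist_hz(self) -> float:
        return float(self.freqs[-1])


@dataclasses.dataclass
class AmplitudeMap:
    """3D amplitude image with provenance.

    ``kind`` is one of ``A_raw`` (unnormalised band amplitude),
    ``ALFF_normalized`` (subject-mean normalisation) or ``fALFF``.
    """

    values: np.ndarray
    kind: str
    brain_mask: np.ndarray
    band_hz: tuple[float, float] = DEFAULT_BAND
    regressed: bool = False
    n_in_brain: int = 0
    fwhm_mm: float = 0.0
    voxel_sizes_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    subject_id: str = ""


def linear_detrend(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line (over the last axis)."""
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    if n < 3:
        raise ValueError("need at least 3 frames to detrend")
    t = np.arange(n, dtype=np.float64)
    t = (t - t.mean()) / t.std()
    flat = series.reshape(-1, n)
    slope = flat @ t / n  # t has unit variance, zero mean
    resid = flat - flat.mean(axis=1, keepdims=True) - np.outer(slope, t)
    return resid.reshape(series.shape)


def amplitude_spectrum(series: np.ndarray, tr_seconds: float) -> AmplitudeSpectrum:
    """One-sided amplitude spectrum of an (already detrended) series."""
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    amps = _one_sided_amplitudes(series[np.newaxis, :] if series.ndim == 1 else series)
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    return AmplitudeSpectrum(freqs=freqs, amplitudes=amps[0] if series.ndim == 1 else amps)


def _one_sided_amplitudes(flat: np.ndarray) -> np.ndarray:
    """a_k per row: c_k |rfft|/N with c=1 at DC and even-N Nyquist, else 2."""
    n = flat.shape[-1]
    spec = np.abs(np.fft.rfft(flat, axis=-1)) / n
    coef = np.full(spec.shape[-1], 2.0)
    coef[0] = 1.0
    if n % 2 == 0:
        coef[-1] = 1.0
    return spec * coef


def band_mask(freqs: np.ndarray, f_lo: float, f_hi: float) -> np.ndarray:
    return (freqs >= f_lo - _FREQ_TOL) & (freqs <= f_hi + _FREQ_TOL)


def band_amplitude(
    spectrum: AmplitudeSpectrum,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
) -> float:
    """Mean amplitude over in-band bins (inclusive bounds): the A_i statistic."""
    sel = band_mask(spectrum.freqs, f_lo, f_hi)
    if not sel.any():
        n = 2 * (len(spectrum.freqs) - 1)
        raise ValueError(
            f"no DFT bins inside band [{f_lo}, {f_hi}] Hz "
            f"(N~{n}, nyquist={spectrum.nyquist_hz:.4g} Hz)"
        )
    return float(np.mean(spectrum.amplitudes[sel]))


def _voxel_band_stats(run: BoldRun, f_lo: float, f_hi: float):
    """Per in-brain voxel: (A_i, band amplitude sum, total non-DC amplitude sum)."""
    flat = run.data[run.brain_mask]  # (V, t)
    resid = linear_detrend(flat)
    amps = _one_sided_amplitudes(resid)
    freqs = np.fft.rfftfreq(run.n_frames, d=run.tr_seconds)
    sel = band_mask(freqs, f_lo, f_hi)
    if not sel.any():
        raise ValueError(
            f"no DFT bins inside band [{f_lo}, {f_hi}] Hz "
            f"(N={run.n_frames}, TR={run.tr_seconds})"
        )
    a_mean = amps[:, sel].mean(axis=1)
    band_sum = amps[:, sel].sum(axis=1)
    total_sum = amps[:, 1:].sum(axis=1)  # exclude DC
    return a_mean, band_sum, total_sum


def compute_alff_map(
    run: BoldRun,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    regressed: bool = False,
) -> tuple[AmplitudeMap, AmplitudeMap]:
    """Subject-normalised ALFF map plus the raw band-amplitude map.

    Returns ``(alff_normalized, a_raw)``.  The normalised map divides each
    voxel's A_i by the in-brain mean of A, so its in-brain mean is exactly 1
    and any global rescaling of the run cancels.
    """
    if not run.brain_mask.any():
        raise ValueError("brain mask is empty")
    a_mean, _, _ = _voxel_band_stats(run, f_lo, f_hi)
    grand = a_mean.mean()
    if grand == 0:
        raise ValueError("degenerate run: whole-brain mean band amplitude is 0")
    raw = np.zeros(run.spatial_shape)
    raw[run.brain_mask] = a_mean
    norm = np.zeros(run.spatial_shape)
    norm[run.brain_mask] = a_mean / grand
    common = dict(
        brain_mask=run.brain_mask,
        band_hz=(f_lo, f_hi),
        regressed=regressed,
        n_in_brain=int(run.brain_mask.sum()),
        voxel_sizes_mm=run.voxel_sizes_mm,
        subject_id=run.subject_id,
    )
    return (
        AmplitudeMap(values=norm, kind="ALFF_normalized", **common),
        AmplitudeMap(values=raw, kind="A_raw", **common),
    )


def compute_falff_map(
    run: BoldRun,
    f_lo: float = DEFAULT_BAND[0],
    f_hi: float = DEFAULT_BAND[1],
    regressed: bool = False,
    denominator: str = "amplitude",
) -> AmplitudeMap:
    """fALFF: band amplitude sum over total non-DC amplitude sum, in [0, 1].

    ``denominator="power"`` switches both numerator and denominator to summed
    power (squared amplitudes); the default amplitude/amplitude form keeps the
    statistic commensurate with A_i.
    Voxels with zero total amplitude map to 0 (logged).
    """
    if not run.brain_mask.any():
        raise ValueError("brain mask is empty")
    a_mean, band_sum, total_sum = _voxel_band_stats(run, f_lo, f_hi)
    if denominator == "power":
        flat = linear_detrend(run.data[run.brain_mask])
        amps = _one_sided_amplitudes(flat)
        freqs = np.fft.rfftfreq(run.n_frames, d=run.tr_seconds)
        sel = band_mask(freqs, f_lo, f_hi)
        band_sum = (amps[:, sel] ** 2).sum(axis=1)
        total_sum = (amps[:, 1:] ** 2).sum(axis=1)
    elif denominator != "amplitude":
        raise ValueError(f"unknown denominator kind {denominator!r}")
    out = np.zeros_like(band_sum)
    ok = total_sum > 0
    out[ok] = band_sum[ok] / total_sum[ok]
    n_degenerate = int((~ok).sum())
    if n_degenerate:
        log.warning("fALFF: %d degenerate (zero-amplitude) voxels set to 0", n_degenerate)
    vol = np.zeros(run.spatial_shape)
    vol[run.brain_mask] = out
    return AmplitudeMap(
        values=vol,
        kind="fALFF",
        brain_mask=run.brain_mask,
        band_hz=(f_lo, f_hi),
        regressed=regressed,
        n_in_brain=int(run.brain_mask.sum()),
        voxel_sizes_mm=run.voxel_sizes_mm,
        subject_id=run.subject_id,
    )


def gaussian_smooth(amap: AmplitudeMap, fwhm_mm: float = 8.0) -> AmplitudeMap:
    """Separable 3D Gaussian smoothing of the map (sigma = FWHM / (2*sqrt(2 ln 2))).

    Out-of-brain voxels are zeroed before convolution and the boundary is
    zero-padded (``mode="constant"``), so values near the mask edge shrink
    toward 0 — the usual behaviour when smoothing masked maps.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return dataclasses.replace(amap, fwhm_mm=0.0)
    vol = np.where(amap.brain_mask, amap.values, 0.0)
    sigma_vox = [
        fwhm_mm / (vs * 2.0 * np.sqrt(2.0 * np.log(2.0)))
        for vs in amap.voxel_sizes_mm
    ]
    smoothed = ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant")
    return dataclasses.replace(amap, values=smoothed, fwhm_mm=float(fwhm_mm))
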