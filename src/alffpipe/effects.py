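"""Effect sizes and the mega- vs. meta-analysis comparison.

Per-site diagnosis t-maps are converted to Cohen's d with the two-sample
formula d = t * sqrt(1/n1 + 1/n2) and combined as a sample-size-weighted mean
image.  The pooled ("mega") analysis models all subjects together with site as
a factor; if the per-site ("meta") ROI-mean d is systematically larger than the
mega one, pooling across sites has cost power.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .stats import StatMap


@dataclasses.dataclass
class EffectSizeMap:
    """Cohen's d image; positive = first-named group of the contrast larger."""

    d: np.ndarray
    n1: int
    n2: int
    source: str = "mega"  # "mega", "site:<id>", or "meta"
    contrast: str = ""
    brain_mask: np.ndarray | None = None


def t_to_cohens_d(t_map: StatMap, n1: int, n2: int) -> EffectSizeMap:
    """d = t * sqrt(1/n1 + 1/n2), voxel-wise."""
    if t_map.kind != "t":
        raise ValueError(f"need a t-map, got kind {t_map.kind!r}")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    scale = np.sqrt(1.0 / n1 + 1.0 / n2)
    return EffectSizeMap(
        d=t_map.stat * scale,
        n1=n1,
        n2=n2,
        contrast=t_map.contrast,
        brain_mask=t_map.brain_mask,
    )


def weighted_meta_d(site_maps: list[EffectSizeMap], site_n: list[float]) -> EffectSizeMap:
    """Per-voxel weighted mean of site d-maps, weights = total per-site n."""
    if len(site_maps) < 2:
        raise ValueError("need at least 2 sites for a meta-analytic map")
    if len(site_maps) != len(site_n):
        raise ValueError("one weight per site map required")
    if any(w <= 0 for w in site_n):
        raise ValueError("site weights must be positive")
    shapes = {m.d.shape for m in site_maps}
    if len(shapes) > 1:
        raise ValueError(f"site maps on different grids: {shapes}")
    contrasts = {m.contrast for m in site_maps}
    if len(contrasts) > 1:
        raise ValueError(f"site maps carry different contrasts: {contrasts}")
    w = np.asarray(site_n, dtype=float)
    stack = np.stack([m.d for m in site_maps], axis=0)
    meta = np.tensordot(w, stack, axes=1) / w.sum()
    return EffectSizeMap(
        d=meta,
        n1=sum(m.n1 for m in site_maps),
        n2=sum(m.n2 for m in site_maps),
        source="meta",
        contrast=site_maps[0].contrast,
        brain_mask=site_maps[0].brain_mask,
    )


def roi_mean_d(emap: EffectSizeMap, roi: np.ndarray) -> float:
    roi = np.asarray(roi).astype(bool)
    if roi.shape != emap.d.shape:
        raise ValueError("ROI is not on the map grid")
    if not roi.any():
        raise ValueError("ROI is empty")
    return float(emap.d[roi].mean())


def compare_mega_meta(
    mega: EffectSizeMap,
    meta: EffectSizeMap,
    roi: np.ndarray,
    site_maps: list[EffectSizeMap] | None = None,
) -> dict:
    """ROI-mean d for both analyses, their ratio, and the per-site range."""
    if mega.contrast != meta.contrast:
        raise ValueError(
            f"contrast mismatch: mega={mega.contrast!r}, meta={meta.contrast!r}"
        )
    d_mega = roi_mean_d(mega, roi)
    d_meta = roi_mean_d(meta, roi)
    report = {
        "contrast": mega.contrast,
        "roi_mean_d_mega": d_mega,
        "roi_mean_d_meta": d_meta,
        "ratio_meta_over_mega": d_meta / d_mega if d_mega != 0 else np.inf,
    }
    if site_maps:
        per_site = [roi_mean_d(m, roi) for m in site_maps]
        report["site_d_min"] = min(per_site)
        report["site_d_max"] = max(per_site)
    return report
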