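"""End-to-end study drivers over synthetic cohorts.

Each function generates a cohort (streaming subject by subject, so memory
stays flat), runs the relevant pipeline stages, and returns the summary
numbers.  These are the entry points the analysis scripts, the test suite,
and the acceptance script share.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import qc as qcmod
from .cohort import (
    CohortSpec,
    iter_cohort,
    phantom_masks,
    tissue_probability_maps,
)
from .effects import t_to_cohens_d, weighted_meta_d
from .nuisance import TissueMasks, build_tissue_masks, regress_nuisance
from .spectral import AmplitudeMap, compute_alff_map, compute_falff_map, gaussian_smooth
from .stats import (
    DesignInfo,
    build_design,
    fit_voxelwise_glm,
    paired_ttest_maps,
    threshold_stat_map,
)


@dataclasses.dataclass
class CohortMaps:
    """Per-subject amplitude maps plus the subject table, in roster order."""

    table: pd.DataFrame
    alff: list[AmplitudeMap]
    falff: list[AmplitudeMap]
    alff_reg: list[AmplitudeMap]
    falff_reg: list[AmplitudeMap]
    qc_report: pd.DataFrame
    brain_mask: np.ndarray
    gm_mask: np.ndarray


def cohort_tissue_masks(spec: CohortSpec) -> TissueMasks:
    """WM/CSF masks via the production path: fine-grid probability maps,
    strict > 0.99 threshold, nearest-neighbour resampling to the BOLD grid."""
    wm_prob, csf_prob = tissue_probability_maps(spec.shape)
    return build_tissue_masks(wm_prob, csf_prob, spec.shape)


def compute_cohort_maps(
    spec: CohortSpec,
    regress: bool = False,
    apply_qc: bool = False,
    fwhm_mm: float = 0.0,
) -> CohortMaps:
    """Generate the cohort and compute (optionally regressed) amplitude maps.

    With ``apply_qc`` the default SFNR/motion exclusion rule is applied first
    and only retained subjects contribute maps.
    """
    masks = phantom_masks(spec.shape)
    tissues = cohort_tissue_masks(spec) if regress else None
    rows, qc_rows = [], []
    alff, falff, alff_reg, falff_reg = [], [], [], []
    for record, run, trace in iter_cohort(spec):
        res = qcmod.qc_subject(run, trace)
        retained = True
        if apply_qc:
            _, excluded = qcmod.apply_qc([(record, res)])
            retained = not excluded
        qc_rows.append(
            {
                "subject_id": record.subject_id,
                "site_id": record.site_id,
                "diagnosis": record.diagnosis,
                "sfnr": res.sfnr,
                "max_abs_translation_mm": res.max_abs_translation_mm,
                "mean_fd_mm": res.mean_fd_mm,
                "passed": retained,
                "reasons": ";".join(res.reasons),
            }
        )
        if not retained:
            continue
        rows.append(
            {
                "subject_id": record.subject_id,
                "site_id": record.site_id,
                "diagnosis": record.diagnosis,
                "age_years": record.age_years,
                "sex": record.sex,
            }
        )
        a, _ = compute_alff_map(run, *spec.band_hz)
        f = compute_falff_map(run, *spec.band_hz)
        if fwhm_mm > 0:
            a, f = gaussian_smooth(a, fwhm_mm), gaussian_smooth(f, fwhm_mm)
        alff.append(a)
        falff.append(f)
        if regress:
            resid = regress_nuisance(run, trace, tissues)
            ar, _ = compute_alff_map(resid, *spec.band_hz, regressed=True)
            fr = compute_falff_map(resid, *spec.band_hz, regressed=True)
            if fwhm_mm > 0:
                ar, fr = gaussian_smooth(ar, fwhm_mm), gaussian_smooth(fr, fwhm_mm)
            alff_reg.append(ar)
            falff_reg.append(fr)
    return CohortMaps(
        table=pd.DataFrame(rows),
        alff=alff,
        falff=falff,
        alff_reg=alff_reg,
        falff_reg=falff_reg,
        qc_report=pd.DataFrame(qc_rows),
        brain_mask=masks["brain"],
        gm_mask=masks["gm"],
    )


# --------------------------------------------------------------------------
# Studies


def null_rejection_rate(spec: CohortSpec, measure: str = "alff") -> float:
    """Fraction of in-brain voxels where the two-sided diagnosis test rejects
    at uncorrected p < 0.05, on a cohort with no injected effect."""
    maps = compute_cohort_maps(spec)
    design = build_design(maps.table)
    glm = fit_voxelwise_glm(getattr(maps, measure), design, maps.brain_mask)
    smap = glm["dx_t_SZgtHC"]
    t = smap.stat[maps.brain_mask]
    p_two = 2.0 * sps.t.sf(np.abs(t), smap.df[0])
    return float((p_two < 0.05).mean())


def run_null_study(
    n_reps: int = 20, seed: int = 0, spec_kwargs: dict | None = None
) -> dict:
    """Type-I-error calibration of the diagnosis contrast over replicate cohorts."""
    from .cohort import null_spec

    rates = [
        null_rejection_rate(null_spec(master_seed=seed + rep, **(spec_kwargs or {})))
        for rep in range(n_reps)
    ]
    return {"rates": rates, "mean_rate": float(np.mean(rates)), "n_reps": n_reps}


def run_recovery_study(spec: CohortSpec, q: float = 0.05, k_min: int = 10) -> dict:
    """Sensitivity / specificity of FDR+extent-thresholded diagnosis maps
    against the injected effect regions (ALFF, unsmoothed)."""
    region_masks = {r.name: r.mask(spec.shape) for r in spec.regions}
    contrast_for = {
        name: ("dx_t_HCgtSZ" if spec_region.ratio < 1 else "dx_t_SZgtHC")
        for name, spec_region in ((r.name, r) for r in spec.regions)
    }
    maps = compute_cohort_maps(spec)
    design = build_design(maps.table)
    glm = fit_voxelwise_glm(maps.alff, design, maps.brain_mask)
    sig = {
        key: threshold_stat_map(glm[key], q=q, k_min=k_min).sig_mask
        for key in ("dx_t_HCgtSZ", "dx_t_SZgtHC")
    }
    effect_union = np.zeros(spec.shape, dtype=bool)
    hit = total = 0
    for name, mask in region_masks.items():
        effect_union |= mask
        hit += int((sig[contrast_for[name]] & mask).sum())
        total += int(mask.sum())
    outside = maps.brain_mask & ~effect_union
    fp = int(((sig["dx_t_HCgtSZ"] | sig["dx_t_SZgtHC"]) & outside).sum())
    return {
        "sensitivity": hit / total,
        "false_positive_rate": fp / int(outside.sum()),
        "n_effect_voxels": total,
        "n_outside_voxels": int(outside.sum()),
        "n_subjects": len(maps.table),
    }


def mega_meta_effects(
    spec: CohortSpec, roi: np.ndarray, measure: str = "alff"
) -> dict:
    """Mega- and meta-analytic ROI-mean Cohen's d for the SZ>HC contrast."""
    from .effects import compare_mega_meta, roi_mean_d

    maps = compute_cohort_maps(spec)
    stack = getattr(maps, measure)
    table = maps.table

    design = build_design(table)
    glm = fit_voxelwise_glm(stack, design, maps.brain_mask)
    mega = t_to_cohens_d(glm["dx_t_SZgtHC"], design.n_hc, design.n_sz)
    mega.source = "mega"

    site_maps, site_n = [], []
    for site in sorted(set(table["site_id"])):
        sel = (table["site_id"] == site).to_numpy()
        sub_table = table[sel].reset_index(drop=True)
        sub_stack = [m for m, keep in zip(stack, sel) if keep]
        sdesign = build_design(sub_table, include_site=False)
        sglm = fit_voxelwise_glm(sub_stack, sdesign, maps.brain_mask)
        smap = t_to_cohens_d(sglm["dx_t_SZgtHC"], sdesign.n_hc, sdesign.n_sz)
        smap.source = f"site:{site}"
        site_maps.append(smap)
        site_n.append(len(sub_table))
    meta = weighted_meta_d(site_maps, site_n)

    report = compare_mega_meta(mega, meta, roi, site_maps=site_maps)
    report["site_d"] = {m.source: roi_mean_d(m, roi) for m in site_maps}
    return report


def run_megameta_study(
    d_target: float = 0.8, n_reps: int = 10, seed: int = 0, **spec_kwargs
) -> dict:
    """Replicate mega/meta comparisons on homogeneous-effect cohorts."""
    from .cohort import megameta_spec

    reports = []
    for rep in range(n_reps):
        spec = megameta_spec(d_target=d_target, master_seed=seed + rep, **spec_kwargs)
        roi = next(r for r in spec.regions if r.name == "anterior").mask(spec.shape)
        reports.append(mega_meta_effects(spec, roi))
    return {
        "d_target": d_target,
        "mean_d_mega": float(np.mean([r["roi_mean_d_mega"] for r in reports])),
        "mean_d_meta": float(np.mean([r["roi_mean_d_meta"] for r in reports])),
        "mean_ratio": float(np.mean([r["ratio_meta_over_mega"] for r in reports])),
        "reports": reports,
    }


def paired_regression_direction(spec: CohortSpec) -> dict:
    """Paired t of original − regressed fALFF; positive mean over GM means the
    regression lowered fALFF (the expected direction under aliased in-band
    physiology)."""
    maps = compute_cohort_maps(spec, regress=True)
    smap = paired_ttest_maps(maps.falff, maps.falff_reg, maps.brain_mask)
    gm_t = smap.stat[maps.gm_mask]
    return {
        "mean_t_gm": float(gm_t.mean()),
        "frac_positive_gm": float((gm_t > 0).mean()),
        "n_subjects": len(maps.table),
    }


def run_paired_direction_study(
    n_seeds: int = 10, seed: int = 0, n_per_group: int = 6
) -> dict:
    """Direction of the regression effect on fALFF across replicate cohorts."""
    from .cohort import CohortSpec, study_sites

    means = []
    for rep in range(n_seeds):
        spec = CohortSpec(
            sites=study_sites(n_sites=1, n_per_group=n_per_group, vendor_outlier=False),
            master_seed=seed + rep,
        )
        means.append(paired_regression_direction(spec)["mean_t_gm"])
    return {
        "mean_t_per_seed": means,
        "n_positive": int(np.sum(np.array(means) > 0)),
        "n_seeds": n_seeds,
    }
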