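"""Voxel-wise group statistics.

Two inferential paths:

* a paired t-test across subjects (e.g. original vs. regressed amplitude
  maps), and
* a per-voxel OLS GLM with site (dummy-coded, last site as implicit
  baseline), diagnosis (HC=0, SZ=1), mean-centred age, and the age x
  diagnosis interaction.  The site main effect is a partial F
  (extra-sum-of-squares against the model without the site columns); the
  diagnosis effect is reported as the two one-sided contrasts HC>SZ and
  SZ>HC.

Significance masks use Benjamini–Hochberg FDR over in-brain voxels followed
by a cluster-extent filter (components of >= k voxels under 18-connectivity
by default).  Voxels with zero variance get t=0, p=1 so map algebra stays
total.
"""
from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("alffpipe")

DEFAULT_Q = 0.05
DEFAULT_EXTENT = 10
DEFAULT_CONNECTIVITY = 18
STAT_CAP = 1e6  # reported statistic for numerically perfect fits

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass
class StatMap:
    """Voxel-wise statistic image with p-values and (optional) significance mask."""

    stat: np.ndarray
    kind: str  # "t" or "F"
    df: tuple
    p: np.ndarray
    brain_mask: np.ndarray
    contrast: str = ""
    sig_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("t", "F"):
            raise ValueError(f"kind must be 't' or 'F', got {self.kind!r}")
        inb = self.p[self.brain_mask]
        if not np.all(np.isfinite(inb)) or inb.min() < 0 or inb.max() > 1:
            raise ValueError("p-values must be finite and in [0, 1] in-brain")


@dataclasses.dataclass
class DesignInfo:
    """Subject-level design for the voxel-wise GLM."""

    matrix: np.ndarray
    columns: list[str]
    n_hc: int
    n_sz: int
    site_columns: list[str]
    diagnosis_column: str = "diagnosis"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_design(
    table: pd.DataFrame,
    baseline_site: str | None = None,
    include_site: bool = True,
) -> DesignInfo:
    """Dummy-code the subject table into a GLM design.

    Site levels are sorted; the baseline (reference) site defaults to the last
    level.  Age is mean-centred before the interaction is formed so the
    diagnosis main effect is evaluated at the mean age.
    """
    diag = table["diagnosis"].to_numpy()
    bad = set(diag) - {"HC", "SZ"}
    if bad:
        raise ValueError(f"unknown diagnosis labels {sorted(bad)}")
    dx = (diag == "SZ").astype(float)
    n_sz = int(dx.sum())
    n_hc = len(dx) - n_sz
    if n_hc < 2 or n_sz < 2:
        raise ValueError("need at least 2 subjects per diagnosis group")
    age = table["age_years"].to_numpy(dtype=float)
    age_c = age - age.mean()

    sites = sorted(set(table["site_id"].astype(str)))
    cols = [np.ones(len(dx))]
    names = ["intercept"]
    site_cols: list[str] = []
    if include_site and len(sites) > 1:
        if baseline_site is None:
            baseline_site = sites[-1]
        elif baseline_site not in sites:
            raise ValueError(f"baseline site {baseline_site!r} not among sites {sites}")
        for s in sites:
            if s == baseline_site:
                continue
            cols.append((table["site_id"].astype(str).to_numpy() == s).astype(float))
            names.append(f"site_{s}")
            site_cols.append(f"site_{s}")
    elif include_site and len(sites) <= 1:
        log.info("single site in design; site factor dropped")
    cols += [dx, age_c, age_c * dx]
    names += ["diagnosis", "age", "age_x_diagnosis"]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return DesignInfo(
        matrix=X, columns=names, n_hc=n_hc, n_sz=n_sz, site_columns=site_cols
    )


def _stack_to_matrix(maps, brain_mask) -> np.ndarray:
    vols = [m.values if hasattr(m, "values") else np.asarray(m) for m in maps]
    return np.stack([v[brain_mask] for v in vols], axis=0)  # (n, V)


def paired_ttest_maps(maps_a, maps_b, brain_mask) -> StatMap:
    """Per-voxel paired t-test of a - b across subjects (same order)."""
    a = _stack_to_matrix(maps_a, brain_mask)
    b = _stack_to_matrix(maps_b, brain_mask)
    if a.shape != b.shape:
        raise ValueError("map stacks differ in shape")
    n = a.shape[0]
    if n < 3:
        raise ValueError("paired t-test needs at least 3 subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n))
    df = n - 1
    p = np.ones_like(mean)
    p[ok] = 2.0 * sps.t.sf(np.abs(t[ok]), df)
    return StatMap(
        stat=_unflatten(t, brain_mask),
        kind="t",
        df=(df,),
        p=_unflatten(p, brain_mask, fill=1.0),
        brain_mask=brain_mask,
        contrast="a_minus_b",
    )


def _unflatten(values: np.ndarray, brain_mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    vol = np.full(brain_mask.shape, fill, dtype=np.float64)
    vol[brain_mask] = values
    return vol


def fit_voxelwise_glm(maps, design: DesignInfo, brain_mask) -> dict[str, StatMap]:
    """Ordinary least squares per voxel; returns the contrast maps of interest.

    Keys: ``dx_t_HCgtSZ``, ``dx_t_SZgtHC`` (one-sided p), ``age_t``,
    ``interaction_t`` (two-sided p) and, when the design has site columns,
    ``site_F`` (partial F, extra sum of squares).
    """
    Y = _stack_to_matrix(maps, brain_mask)  # (n, V)
    X = design.matrix
    n, p_cols = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"{Y.shape[0]} maps but design has {n} rows")
    if n <= p_cols + 2:
        raise ValueError(f"too few subjects (n={n}) for {p_cols} design columns")
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y  # (p, V)
    resid = Y - X @ beta
    df_resid = n - p_cols
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df_resid
    xtx_inv = pinv @ pinv.T

    # degenerate-voxel convention: zero-variance or numerically perfect fits
    # get t=0/p=1 for a null coefficient and a capped statistic otherwise
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    perfect = rss <= 1e-20 * np.maximum(ss_tot, 1e-300)
    beta_floor = 1e-8 * np.sqrt(ss_tot / n + 1e-300)

    def t_map(col: str, side: str, label: str) -> StatMap:
        j = design.columns.index(col)
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 0.0))
        t = np.zeros(Y.shape[1])
        ok = (se > 0) & ~perfect
        t[ok] = beta[j, ok] / se[ok]
        capped = perfect & (np.abs(beta[j]) > beta_floor)
        t[capped] = np.sign(beta[j, capped]) * STAT_CAP
        if side == "neg":
            t = -t
        p = np.ones(Y.shape[1])
        live = ok | capped
        if side == "two":
            p[live] = 2.0 * sps.t.sf(np.abs(t[live]), df_resid)
        else:
            p[live] = sps.t.sf(t[live], df_resid)
        return StatMap(
            stat=_unflatten(t, brain_mask),
            kind="t",
            df=(df_resid,),
            p=_unflatten(p, brain_mask, fill=1.0),
            brain_mask=brain_mask,
            contrast=label,
        )

    out = {
        "dx_t_SZgtHC": t_map("diagnosis", "pos", "SZ>HC"),
        "dx_t_HCgtSZ": t_map("diagnosis", "neg", "HC>SZ"),
        "age_t": t_map("age", "two", "age"),
        "interaction_t": t_map("age_x_diagnosis", "two", "age_x_diagnosis"),
    }

    if design.site_columns:
        keep = [i for i, c in enumerate(design.columns) if c not in design.site_columns]
        Xr = X[:, keep]
        beta_r = np.linalg.pinv(Xr) @ Y
        rss_r = ((Y - Xr @ beta_r) ** 2).sum(axis=0)
        q = len(design.site_columns)
        F = np.zeros(Y.shape[1])
        ok = ~perfect
        F[ok] = ((rss_r[ok] - rss[ok]) / q) / (rss[ok] / df_resid)
        F = np.maximum(F, 0.0)
        capped = perfect & (rss_r - rss > 1e-16 * np.maximum(ss_tot, 1e-300))
        F[capped] = STAT_CAP
        pF = np.ones(Y.shape[1])
        live = ok | capped
        pF[live] = sps.f.sf(F[live], q, df_resid)
        out["site_F"] = StatMap(
            stat=_unflatten(F, brain_mask),
            kind="F",
            df=(q, df_resid),
            p=_unflatten(pF, brain_mask, fill=1.0),
            brain_mask=brain_mask,
            contrast="site",
        )
    return out


def fdr_threshold(p: np.ndarray, brain_mask: np.ndarray, q: float = DEFAULT_Q) -> np.ndarray:
    """Benjamini–Hochberg step-up over in-brain voxels; returns a binary mask."""
    pv = p[brain_mask]
    if pv.size == 0:
        return np.zeros_like(brain_mask)
    reject, *_ = multipletests(pv, alpha=q, method="fdr_bh")
    out = np.zeros(brain_mask.shape, dtype=bool)
    out[brain_mask] = reject
    return out


def cluster_extent_filter(
    mask: np.ndarray,
    k_min: int = DEFAULT_EXTENT,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> np.ndarray:
    """Keep connected components with at least ``k_min`` voxels."""
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_STRUCTS)}")
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_CONNECTIVITY_STRUCTS[connectivity])
    if n == 0:
        return np.zeros_like(mask)
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= k_min)
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def threshold_stat_map(
    smap: StatMap,
    q: float = DEFAULT_Q,
    k_min: int = DEFAULT_EXTENT,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> StatMap:
    """FDR + cluster-extent significance mask, stored on the map."""
    sig = fdr_threshold(smap.p, smap.brain_mask, q=q)
    sig = cluster_extent_filter(sig, k_min=k_min, connectivity=connectivity)
    return dataclasses.replace(smap, sig_mask=sig)


def cluster_table(smap: StatMap, connectivity: int = DEFAULT_CONNECTIVITY) -> pd.DataFrame:
    """Label, size, peak statistic and peak voxel index of each significant cluster."""
    if smap.sig_mask is None:
        raise ValueError("stat map has no significance mask; run threshold_stat_map first")
    labels, n = ndimage.label(smap.sig_mask, structure=_CONNECTIVITY_STRUCTS[connectivity])
    rows = []
    for lab in range(1, n + 1):
        sel = labels == lab
        stats_in = np.where(sel, np.abs(smap.stat), -np.inf)
        peak = np.unravel_index(np.argmax(stats_in), labels.shape)
        rows.append(
            {
                "label": lab,
                "size_voxels": int(sel.sum()),
                "peak_stat": float(smap.stat[peak]),
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
            }
        )
    rows.sort(key=lambda r: -abs(r["peak_stat"]))
    return pd.DataFrame(rows, columns=["label", "size_voxels", "peak_stat", "peak_x", "peak_y", "peak_z"])
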