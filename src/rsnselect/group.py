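"""Random-effects group statistics on component beta maps.

Per subject, the BOLD signal is residualized against every component course
except the selected one; regressing the residual on the selected course gives
the subject's beta map (the two-step estimate; by Frisch-Waugh-Lovell it
equals the partial regression coefficient of the full model).  Beta maps
enter one-sample (within-group) and pooled two-sample (contrast) t maps.
Voxelwise inference uses Benjamini-Hochberg FDR; cluster-extent inference
uses a Monte-Carlo estimate of the minimum cluster size controlling the
cluster-wise false-positive rate on smoothness-matched null fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .core import BoldRun
from .preprocess import FWHM_TO_SIGMA

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass
class BetaMap:
    values: np.ndarray          # 3D, zero out-of-mask
    mask: np.ndarray
    subject_id: str = ""
    selected_component: int = -1

    def __post_init__(self):
        if not np.isfinite(self.values[self.mask]).all():
            raise ValueError("non-finite beta values in-mask")


@dataclass
class StatMap:
    tvalues: np.ndarray
    dof: int
    kind: str                   # "one_sample" | "two_sample"
    mask: np.ndarray
    zero_variance: np.ndarray = None   # flagged voxels where t was set to 0

    def __post_init__(self):
        if self.dof < 1:
            raise ValueError("dof must be >= 1")


def residualize(run: BoldRun, courses: np.ndarray, selected: int) -> BoldRun:
    """Residual of every in-mask voxel after OLS on intercept + all
    component courses except the selected one."""
    n_comp = courses.shape[1]
    if not 0 <= selected < n_comp:
        raise ValueError("selected component out of range")
    others = np.delete(courses, selected, axis=1)
    X = np.column_stack([np.ones(run.n_volumes), others])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient nuisance design")
    Q, _ = np.linalg.qr(X)
    Y = run.in_mask()
    resid = Y - Q @ (Q.T @ Y)
    data = run.data.copy()
    data[run.mask] = resid.T
    return run.with_data(data)


def residualize_course(course: np.ndarray, courses: np.ndarray,
                       selected: int) -> np.ndarray:
    """Residualize the selected course against the same nuisance design
    used by :func:`residualize` (intercept + all other courses), so the
    two-step beta equals the full-model partial coefficient exactly
    (Frisch-Waugh-Lovell)."""
    others = np.delete(courses, selected, axis=1)
    X = np.column_stack([np.ones(len(course)), others])
    Q, _ = np.linalg.qr(X)
    return course - Q @ (Q.T @ course)


def component_beta_map(residual: BoldRun, selected_course: np.ndarray,
                       subject_id="", selected_component=-1) -> BetaMap:
    """Voxelwise OLS slope of the residual signal on intercept + the
    selected component course."""
    c = np.asarray(selected_course, dtype=float)
    if c.size != residual.n_volumes:
        raise ValueError("course length mismatch")
    cc = c - c.mean()
    denom = (cc ** 2).sum()
    if denom == 0:
        raise ValueError("constant course")
    Y = residual.in_mask()
    beta = cc @ (Y - Y.mean(axis=0)) / denom
    values = np.zeros(residual.grid_shape)
    values[residual.mask] = beta
    return BetaMap(values=values, mask=residual.mask, subject_id=subject_id,
                   selected_component=selected_component)


def _stack(maps):
    mask = maps[0].mask
    return np.stack([m.values[mask] for m in maps]), mask


def rfx_one_sample(maps) -> StatMap:
    """Voxelwise one-sample t of subject betas against zero; dof = n - 1.
    Zero-variance voxels get t = 0 and are flagged."""
    if len(maps) < 3:
        raise ValueError("need at least 3 subjects")
    B, mask = _stack(maps)
    n = B.shape[0]
    mean = B.mean(axis=0)
    sd = B.std(axis=0, ddof=1)
    zero = sd == 0
    t = np.zeros_like(mean)
    t[~zero] = mean[~zero] / (sd[~zero] / np.sqrt(n))
    tvol = np.zeros(mask.shape)
    tvol[mask] = t
    zvol = np.zeros(mask.shape, dtype=bool)
    zvol[mask] = zero
    return StatMap(tvalues=tvol, dof=n - 1, kind="one_sample", mask=mask,
                   zero_variance=zvol)


def two_sample_contrast(g1, g2) -> StatMap:
    """Pooled-variance two-sample t map (group 1 minus group 2);
    dof = n1 + n2 - 2."""
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 subjects per group")
    B1, mask = _stack(g1)
    B2, _ = _stack(g2)
    n1, n2 = B1.shape[0], B2.shape[0]
    dof = n1 + n2 - 2
    s2 = ((B1.var(axis=0, ddof=1) * (n1 - 1)
           + B2.var(axis=0, ddof=1) * (n2 - 1)) / dof)
    se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    zero = se == 0
    t = np.zeros(B1.shape[1])
    diff = B1.mean(axis=0) - B2.mean(axis=0)
    t[~zero] = diff[~zero] / se[~zero]
    tvol = np.zeros(mask.shape)
    tvol[mask] = t
    zvol = np.zeros(mask.shape, dtype=bool)
    zvol[mask] = zero
    return StatMap(tvalues=tvol, dof=dof, kind="two_sample", mask=mask,
                   zero_variance=zvol)


def fdr_mask(stat: StatMap, q=0.05) -> np.ndarray:
    """Benjamini-Hochberg mask of in-mask voxels surviving FDR q on
    two-sided p-values."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    t = stat.tvalues[stat.mask]
    p = 2.0 * stats.t.sf(np.abs(t), stat.dof)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    out = np.zeros(stat.mask.shape, dtype=bool)
    out[stat.mask] = reject
    return out


def estimate_smoothness_fwhm(maps, voxel_mm) -> float:
    """Estimate the spatial smoothness (Gaussian FWHM, mm) of a set of 3D
    fields from their lag-1 autocorrelation along each axis.

    For white noise smoothed by a Gaussian of width sigma, the field
    autocorrelation at lag d is exp(-d^2 / (4 sigma^2)).
    """
    fwhms = []
    for m in maps:
        vals = m.values if hasattr(m, "values") else m
        for ax in range(3):
            a = np.moveaxis(vals, ax, 0)
            x = a[:-1].ravel()
            y = a[1:].ravel()
            rho = np.corrcoef(x, y)[0, 1]
            if not np.isfinite(rho) or rho <= 0:
                continue
            sigma_vox = np.sqrt(-1.0 / (4.0 * np.log(rho)))
            fwhms.append(sigma_vox / FWHM_TO_SIGMA * voxel_mm[ax])
    return float(np.mean(fwhms)) if fwhms else 0.0


def _null_max_cluster_sizes(shape, z_threshold, sigma_vox, n_iterations, rng):
    sizes = np.empty(n_iterations, dtype=int)
    for i in range(n_iterations):
        f = rng.standard_normal(shape)
        if any(s > 0 for s in sigma_vox):
            f = ndimage.gaussian_filter(f, sigma=sigma_vox)
            f = (f - f.mean()) / f.std()
        best = 0
        for supra in (f > z_threshold, f < -z_threshold):
            if supra.any():
                lab, nlab = ndimage.label(supra, structure=_CONN26)
                if nlab:
                    best = max(best, int(np.bincount(lab.ravel())[1:].max()))
        sizes[i] = best
    return sizes


def cluster_size_threshold(grid_shape, voxel_t_threshold, dof,
                           smoothness_mm=8.0, voxel_mm=(3.0, 3.0, 3.0),
                           n_iterations=1000, alpha=0.05, seed=0) -> int:
    """Monte-Carlo minimum cluster extent controlling the cluster-wise
    false-positive rate.

    Simulates ``n_iterations`` null Gaussian fields smoothed to
    ``smoothness_mm``, thresholds them two-sided at the voxel t threshold
    (applied through the equivalent normal quantile, which yields the same
    suprathreshold set as transforming each voxel to t marginals), records
    the maximum 26-connected cluster size per iteration, and returns the
    smallest size k whose exceedance fraction is <= alpha.
    """
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if voxel_t_threshold <= 0:
        raise ValueError("voxel_t_threshold must be positive")
    z_th = stats.norm.ppf(stats.t.cdf(voxel_t_threshold, dof))
    sigma_vox = tuple(smoothness_mm * FWHM_TO_SIGMA / v for v in voxel_mm)
    rng = np.random.default_rng(seed)
    sizes = _null_max_cluster_sizes(grid_shape, z_th, sigma_vox,
                                    n_iterations, rng)
    for k in range(1, sizes.max() + 2):
        if (sizes >= k).mean() <= alpha:
            return k
    return int(sizes.max() + 1)


def apply_cluster_threshold(stat: StatMap, voxel_t_threshold, min_size=1
                            ) -> pd.DataFrame:
    """Cluster table of suprathreshold 26-connected clusters (positive and
    negative labelled separately) of at least ``min_size`` voxels."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    rows = []
    cluster_id = 0
    for sign, supra in (("positive",
                         (stat.tvalues > voxel_t_threshold) & stat.mask),
                        ("negative",
                         (stat.tvalues < -voxel_t_threshold) & stat.mask)):
        lab, nlab = ndimage.label(supra, structure=_CONN26)
        for li in range(1, nlab + 1):
            vox = lab == li
            size = int(vox.sum())
            if size < min_size:
                continue
            tv = np.where(vox, stat.tvalues, 0.0)
            flat = np.abs(tv).argmax()
            peak = np.unravel_index(flat, tv.shape)
            cluster_id += 1
            rows.append({"cluster_id": cluster_id, "size_voxels": size,
                         "peak_t": float(stat.tvalues[peak]),
                         "peak_i": peak[0], "peak_j": peak[1],
                         "peak_k": peak[2], "sign": sign})
    return pd.DataFrame(rows, columns=["cluster_id", "size_voxels", "peak_t",
                                       "peak_i", "peak_j", "peak_k", "sign"])


class GroupContrast:
    """Random-effects group model on per-subject beta maps.

    Parameters
    ----------
    control_maps, patient_maps : lists of BetaMap
        Patient list may be empty, in which case only the one-sample
        analysis is available.
    voxel_mm : tuple
    """

    def __init__(self, control_maps, patient_maps=(), voxel_mm=(3.0, 3.0, 3.0)):
        self.control_maps = list(control_maps)
        self.patient_maps = list(patient_maps)
        self.voxel_mm = tuple(voxel_mm)

    def fit(self, q_fdr=0.05, voxel_p=0.01, n_iterations=1000,
            alpha_cluster=0.05, seed=0) -> "GroupResults":
        control_stat = rfx_one_sample(self.control_maps)
        patient_stat = (rfx_one_sample(self.patient_maps)
                        if len(self.patient_maps) >= 3 else None)
        contrast = None
        cluster_table = None
        min_size = None
        t_vox = None
        if len(self.patient_maps) >= 2:
            contrast = two_sample_contrast(self.patient_maps,
                                           self.control_maps)
            t_vox = float(stats.t.ppf(1 - voxel_p / 2, contrast.dof))
            # null-field smoothness taken from the statistical map being
            # thresholded (as the randomization plug-in does); this absorbs
            # the extra spatial structure that between-subject anatomical
            # variability adds on top of the acquisition smoothing
            smooth = estimate_smoothness_fwhm([contrast.tvalues],
                                              self.voxel_mm)
            min_size = cluster_size_threshold(
                contrast.mask.shape, t_vox, contrast.dof,
                smoothness_mm=smooth, voxel_mm=self.voxel_mm,
                n_iterations=n_iterations, alpha=alpha_cluster, seed=seed)
            cluster_table = apply_cluster_threshold(contrast, t_vox, min_size)
        return GroupResults(self, control_stat, patient_stat, contrast,
                            fdr_control=fdr_mask(control_stat, q_fdr),
                            cluster_table=cluster_table,
                            min_cluster_size=min_size,
                            voxel_t_threshold=t_vox, q_fdr=q_fdr)


class GroupResults:
    """Fitted group analysis: T maps, FDR masks, and the contrast cluster
    table (when two groups are present)."""

    def __init__(self, model, control_stat, patient_stat, contrast,
                 fdr_control, cluster_table, min_cluster_size,
                 voxel_t_threshold, q_fdr):
        self.model = model
        self.control_stat = control_stat
        self.patient_stat = patient_stat
        self.contrast = contrast
        self.fdr_control = fdr_control
        self.cluster_table = cluster_table
        self.min_cluster_size = min_cluster_size
        self.voxel_t_threshold = voxel_t_threshold
        self.q_fdr = q_fdr

    def summary(self) -> str:
        lines = ["Random-effects group analysis", "=" * 30,
                 f"controls: n={len(self.model.control_maps)}"
                 f" (one-sample dof={self.control_stat.dof}),"
                 f" FDR q={self.q_fdr}:"
                 f" {int(self.fdr_control.sum())} voxels survive"]
        if self.patient_stat is not None:
            lines.append(f"patients: n={len(self.model.patient_maps)}"
                         f" (one-sample dof={self.patient_stat.dof})")
        if self.contrast is not None:
            lines.append(
                f"contrast (patients - controls): dof={self.contrast.dof},"
                f" voxel |t| > {self.voxel_t_threshold:.3f},"
                f" min cluster size {self.min_cluster_size} voxels")
            lines.append(f"surviving clusters: {len(self.cluster_table)}")
            if len(self.cluster_table):
                lines.append(self.cluster_table.to_string(index=False))
        else:
            lines.append("contrast skipped: fewer than 2 patients")
        return "\n".join(lines)
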