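"""Voxel-wise group inference with Monte-Carlo cluster-extent correction.

Covariate adjustment (age, sex, education) is implemented as
pre-residualization: per voxel, the subject values are OLS-regressed on the
centered covariates and the residuals (plus the grand mean) carry forward;
the consumed degrees of freedom are charged to the error df of the
subsequent ANOVA / t tests.

Cluster-extent correction is Monte-Carlo: null fields are thresholded at
the voxel-level p and the largest suprathreshold connected component
recorded; the extent threshold is the smallest cluster size whose null
exceedance probability is at most alpha.  Null fields can be classic
smoothed Gaussian z maps, simulated group statistics of smoothed Gaussian
subjects, or group statistics of subjects resampled from a pool of genuine
null maps (see :func:`monte_carlo_extent_threshold`); the last, which the
pipeline uses, is the only one calibrated for low-df statistic maps of
non-Gaussian subject fields.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import FcdPipeError

CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatResult:
    """A voxel-wise statistic map with degrees of freedom and p values."""

    stat_map: np.ndarray
    stat_kind: str  # 't' or 'F'
    df: tuple
    voxel_p_map: np.ndarray
    mask: np.ndarray


@dataclass
class ClusterTable:
    """Suprathreshold clusters: peak coordinate (mm), extent, peak statistic."""

    table: pd.DataFrame
    label_map: np.ndarray

    def __len__(self) -> int:
        return len(self.table)

    def significant_mask(self) -> np.ndarray:
        return self.label_map > 0


@dataclass
class ClusterNull:
    """Null distribution of maximum cluster extents and the derived
    minimum cluster size controlling family-wise error at ``alpha``."""

    voxel_p: float
    n_iterations: int
    smoothness_fwhm_mm: float
    connectivity: int
    alpha: float
    max_cluster_sizes: np.ndarray
    extent_threshold: int
    seed: int | None = None


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in CONNECTIVITY_RANK:
        raise FcdPipeError(f"connectivity must be one of {sorted(CONNECTIVITY_RANK)}")
    return ndimage.generate_binary_structure(3, CONNECTIVITY_RANK[connectivity])


def _as_stack(maps) -> np.ndarray:
    """Stack per-subject 3D maps into (n_subjects, ...) array."""
    arr = np.asarray(maps, dtype=float)
    if arr.ndim < 2:
        raise FcdPipeError("need a stack of per-subject maps")
    return arr


def _covariate_matrix(covariates) -> np.ndarray | None:
    """Accept None, an (n, c) array, or a DataFrame with a 'sex' column of
    M/F labels (coded 0/1)."""
    if covariates is None:
        return None
    if isinstance(covariates, pd.DataFrame):
        cov = covariates.copy()
        if "sex" in cov.columns and cov["sex"].dtype == object:
            cov["sex"] = (cov["sex"] == "F").astype(float)
        arr = cov.to_numpy(dtype=float)
    else:
        arr = np.asarray(covariates, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
    # constant columns are absorbed by the intercept: drop them (the
    # effective covariate count c shrinks accordingly)
    keep = arr.std(axis=0) > 0
    if not keep.all():
        arr = arr[:, keep]
    return arr if arr.shape[1] else None


def regress_covariates_across_subjects(values, covariates, keep_mean: bool = True):
    """Residualize per-subject values (scalars or maps) on the covariates.

    Returns residuals with the grand mean added back when ``keep_mean``
    (so group contrasts act on covariate-adjusted values on the original
    scale).  Centered covariates are used, hence the centered residuals are
    exactly orthogonal to every covariate.
    """
    vals = np.asarray(values, dtype=float)
    flat = vals.reshape(vals.shape[0], -1)
    cov = _covariate_matrix(covariates)
    if cov is None:
        return vals
    n, c = cov.shape
    if n != flat.shape[0]:
        raise FcdPipeError("covariate rows must match number of subjects")
    if n < c + 2:
        raise FcdPipeError("need at least covariates + 2 subjects")
    centered = cov - cov.mean(axis=0)
    design = np.column_stack([np.ones(n), centered])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FcdPipeError("covariates are collinear (rank-deficient design)")
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    if keep_mean:
        resid = resid + flat.mean(axis=0, keepdims=True)
    return resid.reshape(vals.shape)


def one_sample_t(maps, mask) -> StatResult:
    """Random-effects one-sample t against zero, per voxel (df = n - 1)."""
    stack = _as_stack(maps)
    n = stack.shape[0]
    if n < 2:
        raise FcdPipeError("one-sample t needs n >= 2")
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_var = sd == 0
    if np.any(zero_var & np.asarray(mask, bool)):
        warnings.warn(
            "zero-variance voxel(s) in one-sample t; t set to +/-inf (p=0) "
            "where the mean is nonzero and 0 (p=1) where it is zero",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    degenerate = np.where(mean == 0, 0.0, np.where(mean > 0, np.inf, -np.inf))
    t = np.where(zero_var, degenerate, t)
    p = 2 * stats.t.sf(np.abs(t), df=n - 1)
    mask = np.asarray(mask, bool)
    return StatResult(
        stat_map=np.where(mask, t, 0.0), stat_kind="t", df=(n - 1,),
        voxel_p_map=np.where(mask, p, 1.0), mask=mask,
    )


def one_way_anova(groups, mask, covariates=None) -> StatResult:
    """Per-voxel one-way ANOVA over >= 2 groups on covariate-residualized
    values; df = (k - 1, N - k - c) where c covariates were consumed."""
    groups = [_as_stack(g) for g in groups]
    k = len(groups)
    if k < 2:
        raise FcdPipeError("ANOVA needs at least 2 groups")
    sizes = [g.shape[0] for g in groups]
    if any(s < 2 for s in sizes):
        raise FcdPipeError(f"every group needs >= 2 subjects, got sizes {sizes}")
    stack = np.concatenate(groups, axis=0)
    n_total = stack.shape[0]
    cov = _covariate_matrix(covariates)
    c = 0 if cov is None else cov.shape[1]
    if cov is not None:
        stack = regress_covariates_across_subjects(stack, cov)
    flat = stack.reshape(n_total, -1)

    grand = flat.mean(axis=0)
    ss_between = np.zeros(flat.shape[1])
    ss_within = np.zeros(flat.shape[1])
    offset = 0
    for size in sizes:
        g = flat[offset:offset + size]
        gm = g.mean(axis=0)
        ss_between += size * (gm - grand) ** 2
        ss_within += ((g - gm) ** 2).sum(axis=0)
        offset += size
    df1 = k - 1
    df2 = n_total - k - c
    if df2 < 1:
        raise FcdPipeError("not enough error degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f = np.where(ss_within == 0, np.where(ss_between == 0, 0.0, np.inf), f)
    p = stats.f.sf(f, df1, df2)
    mask = np.asarray(mask, bool)
    shape = stack.shape[1:]
    return StatResult(
        stat_map=np.where(mask, f.reshape(shape), 0.0), stat_kind="F",
        df=(df1, df2), voxel_p_map=np.where(mask, p.reshape(shape), 1.0), mask=mask,
    )


def posthoc_t(group_a, group_b, restrict_mask, covariates=None) -> StatResult:
    """Two-sample pooled-variance t (group_a minus group_b) on
    covariate-residualized values, evaluated inside ``restrict_mask``
    (typically the ANOVA-significant voxels)."""
    a = _as_stack(group_a)
    b = _as_stack(group_b)
    restrict_mask = np.asarray(restrict_mask, bool)
    if not restrict_mask.any():
        warnings.warn("posthoc_t: restriction mask is empty", stacklevel=2)
    n1, n2 = a.shape[0], b.shape[0]
    cov = _covariate_matrix(covariates)
    c = 0 if cov is None else cov.shape[1]
    stack = np.concatenate([a, b], axis=0)
    if cov is not None:
        stack = regress_covariates_across_subjects(stack, cov)
    a, b = stack[:n1], stack[n1:]
    df = n1 + n2 - 2 - c
    if df < 1:
        raise FcdPipeError("not enough error degrees of freedom")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(pooled * (1 / n1 + 1 / n2))
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    p = 2 * stats.t.sf(np.abs(t), df=df)
    return StatResult(
        stat_map=np.where(restrict_mask, t, 0.0), stat_kind="t", df=(df,),
        voxel_p_map=np.where(restrict_mask, p, 1.0), mask=restrict_mask,
    )


def monte_carlo_extent_threshold(
    mask: np.ndarray,
    voxel_p: float = 0.05,
    smoothness_fwhm_mm: float = 8.0,
    voxel_size_mm=3.0,
    connectivity: int = 18,
    alpha: float = 0.05,
    n_iterations: int = 1000,
    seed=0,
    group_sizes=None,
    n_covariates: int = 0,
    field_pool: np.ndarray | None = None,
) -> ClusterNull:
    """Simulate the null distribution of the maximum suprathreshold cluster
    extent and derive the minimum significant cluster size.

    With ``group_sizes=None`` (the classic recipe), each iteration fills the
    mask with unit Gaussian noise, applies the same masked smoothing used on
    the data, re-standardizes within the mask, thresholds at the one-sided
    upper ``voxel_p`` quantile, and records the largest connected component
    under the stated connectivity.

    With ``group_sizes`` given, each iteration instead simulates the actual
    group statistic: one smoothed noise map per subject (centered within
    the mask, the linearized analogue of dividing each subject's map by its
    in-mask mean), ``n_covariates`` random covariates residualized out, a
    one-way ANOVA across the groups, and thresholding of the F map at
    ``voxel_p``.  This matches the spatial roughness of the statistic
    field — a low-df F map decorrelates faster than the smoothed Gaussian
    field it is built from, so the classic Gaussian-field null is
    conservative at small sample sizes.

    With ``field_pool`` additionally given (a (n_pool, x, y, z) stack of
    null subject maps, e.g. FCD maps computed from connectivity-free BOLD
    noise), each iteration draws its subjects from the pool instead of
    synthesizing Gaussian fields.  This matches not only the roughness of
    the statistic field but the full spatial and distributional structure
    of the analyzed maps, and is what the pipeline uses: Gaussian fields
    remain measurably smoother-tailed than FCD maps, whose thresholded-sum
    construction leaves residual conservatism.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise FcdPipeError("mask is empty")
    if not 0 < voxel_p < 1 or not 0 < alpha <= 1:
        raise FcdPipeError("voxel_p must lie in (0,1) and alpha in (0,1]")
    if n_iterations < 100:
        raise FcdPipeError("use at least 100 iterations")
    structure = _structure(connectivity)
    rng = np.random.default_rng(seed)
    max_sizes = np.zeros(n_iterations, dtype=np.int64)

    # masked-smoothing denominator is iteration-independent
    voxel = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size_mm, float)), (3,))
    if smoothness_fwhm_mm > 0:
        from .fcd import FWHM_PER_SIGMA

        sigma_vox = (smoothness_fwhm_mm / FWHM_PER_SIGMA) / voxel
        den = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
        inside = mask & (den > 0)

        def smooth(vol):
            num = ndimage.gaussian_filter(np.where(mask, vol, 0.0), sigma_vox)
            out = np.zeros_like(num)
            out[inside] = num[inside] / den[inside]
            return out
    else:
        def smooth(vol):
            return np.where(mask, vol, 0.0)

    def max_cluster(supra):
        if not supra.any():
            return 0
        labels, n_lab = ndimage.label(supra, structure=structure)
        return int(np.bincount(labels.ravel())[1:].max()) if n_lab else 0

    if group_sizes is None:
        z_thr = stats.norm.isf(voxel_p)
        for it in range(n_iterations):
            sm = smooth(rng.standard_normal(mask.shape))
            vals = sm[mask]
            sd = vals.std()
            if sd > 0:  # a single-voxel mask is already standard normal
                vals = (vals - vals.mean()) / sd
            supra = np.zeros(mask.shape, dtype=bool)
            supra[mask] = vals > z_thr
            max_sizes[it] = max_cluster(supra)
    else:
        group_sizes = [int(s) for s in group_sizes]
        n_sub = sum(group_sizes)
        splits = np.cumsum(group_sizes)[:-1]
        if field_pool is not None:
            field_pool = np.asarray(field_pool, dtype=float)
            if field_pool.shape[0] < n_sub:
                raise FcdPipeError(
                    f"field pool of {field_pool.shape[0]} maps is smaller than "
                    f"the {n_sub} subjects per iteration"
                )
        for it in range(n_iterations):
            if field_pool is not None:
                idx = rng.choice(field_pool.shape[0], size=n_sub, replace=False)
                fields = field_pool[idx]
            else:
                fields = np.stack([
                    smooth(rng.standard_normal(mask.shape)) for _ in range(n_sub)
                ])
                # per-subject in-mask centering: first-order effect of the
                # per-subject global-mean normalization of the data maps
                fields -= fields[:, mask].mean(axis=1)[:, None, None, None]
            cov = (rng.standard_normal((n_sub, n_covariates))
                   if n_covariates else None)
            anova = one_way_anova(np.split(fields, splits), mask, covariates=cov)
            max_sizes[it] = max_cluster(mask & (anova.voxel_p_map < voxel_p))
    # smallest k with P(max cluster >= k) <= alpha
    sorted_sizes = np.sort(max_sizes)
    k = 1
    while (sorted_sizes >= k).mean() > alpha:
        k += 1
    return ClusterNull(
        voxel_p=voxel_p, n_iterations=n_iterations,
        smoothness_fwhm_mm=smoothness_fwhm_mm, connectivity=connectivity,
        alpha=alpha, max_cluster_sizes=max_sizes, extent_threshold=int(k),
        seed=seed if isinstance(seed, int) else None,
    )


def extract_clusters(
    stat: StatResult,
    voxel_p: float = 0.05,
    extent_threshold: int = 1,
    connectivity: int = 18,
    voxel_size_mm=3.0,
    direction: str = "two-sided",
) -> ClusterTable:
    """Connected suprathreshold components with extent >= extent_threshold.

    ``direction``: 'two-sided' keeps all voxels with p < voxel_p; 'pos' /
    'neg' additionally require the statistic's sign (for signed t maps).
    Peak = voxel with the largest |statistic| (largest t for 'pos', most
    negative for 'neg'); ties broken by lowest linear voxel index.
    """
    voxel = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size_mm, float)), (3,))
    supra = stat.mask & (stat.voxel_p_map < voxel_p)
    if direction == "pos":
        supra &= stat.stat_map > 0
    elif direction == "neg":
        supra &= stat.stat_map < 0
    elif direction != "two-sided":
        raise FcdPipeError("direction must be 'two-sided', 'pos' or 'neg'")
    labels, n_lab = ndimage.label(supra, structure=_structure(connectivity))
    rows = []
    out_labels = np.zeros_like(labels)
    next_id = 0
    key = stat.stat_map if direction == "pos" else (
        -stat.stat_map if direction == "neg" else np.abs(stat.stat_map)
    )
    for lab in range(1, n_lab + 1):
        voxels = labels == lab
        extent = int(voxels.sum())
        if extent < extent_threshold:
            continue
        next_id += 1
        out_labels[voxels] = next_id
        masked = np.where(voxels, key, -np.inf)
        peak_idx = np.unravel_index(int(np.argmax(masked)), labels.shape)
        rows.append({
            "cluster_id": next_id,
            "peak_x_mm": peak_idx[0] * voxel[0],
            "peak_y_mm": peak_idx[1] * voxel[1],
            "peak_z_mm": peak_idx[2] * voxel[2],
            "extent_voxels": extent,
            "extent_mm3": extent * float(np.prod(voxel)),
            "peak_stat": float(stat.stat_map[peak_idx]),
        })
    cols = ["cluster_id", "peak_x_mm", "peak_y_mm", "peak_z_mm",
            "extent_voxels", "extent_mm3", "peak_stat"]
    return ClusterTable(table=pd.DataFrame(rows, columns=cols), label_map=out_labels)
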