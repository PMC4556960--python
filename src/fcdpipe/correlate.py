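"""Regional mean FCD extraction and covariate-adjusted Spearman correlation.

Mean FCD over each cluster that differed among the groups is correlated
with clinical scores (NCT-A, DST, ammonia, ...) within each patient group
separately, using partial Spearman correlation: both variables are
rank-transformed (midranks for ties), the covariates (age, sex 0/1,
education) are regressed out of both rank vectors, and the Pearson
correlation of the residuals is reported with a t-approximation p value on
n - 2 - c degrees of freedom.  Multiple comparisons across regions are
controlled with a Bonferroni cutoff alpha / n_regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .images import FcdPipeError


def extract_region_means(maps, label_map: np.ndarray) -> pd.DataFrame:
    """Mean map value per labelled region, per subject.

    ``maps``: sequence of per-subject 3D maps; ``label_map``: integer labels
    (0 = background).  Returns a subjects x regions DataFrame with columns
    ``region_<id>``.
    """
    label_map = np.asarray(label_map)
    region_ids = sorted(int(r) for r in np.unique(label_map) if r > 0)
    if not region_ids:
        raise FcdPipeError("label map contains no regions")
    cols = {}
    masks = {r: label_map == r for r in region_ids}
    for r, m in masks.items():
        if not m.any():
            raise FcdPipeError(f"region {r} is empty")
    for r in region_ids:
        cols[f"region_{r}"] = [float(np.asarray(m)[masks[r]].mean()) for m in maps]
    for r in region_ids:
        if label_map.shape != np.asarray(maps[0]).shape:
            raise FcdPipeError("label map is not aligned with the FCD grid")
    return pd.DataFrame(cols)


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.asarray(x, float), method="average")


def partial_spearman(x, y, covariates=None, method: str = "t"):
    """Spearman correlation of x and y after regressing covariates out of
    both rank vectors.

    With no covariates this equals the ordinary Spearman rho.  ``method``:
    't' (default) uses the t approximation with df = n - 2 - c; 'permutation'
    computes an exact permutation p over all orderings (small n only, n <= 8).
    Returns (rho, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if len(y) != n:
        raise FcdPipeError("x and y must have equal length")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise FcdPipeError("x and y must be non-constant (ranks undefined)")
    from .groupstats import _covariate_matrix

    cov = _covariate_matrix(covariates)
    c = 0 if cov is None else cov.shape[1]
    if n < c + 3:
        raise FcdPipeError(f"need at least {c + 3} observations with {c} covariates")

    def residual_corr(rx, ry):
        if cov is not None:
            design = np.column_stack([np.ones(n), cov - cov.mean(axis=0)])
            coef, *_ = np.linalg.lstsq(design, np.column_stack([rx, ry]), rcond=None)
            res = np.column_stack([rx, ry]) - design @ coef
            rx, ry = res[:, 0], res[:, 1]
        else:
            rx, ry = rx - rx.mean(), ry - ry.mean()
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        if denom == 0:
            raise FcdPipeError("residual vector is zero; correlation undefined")
        return float(np.dot(rx, ry) / denom)

    rx, ry = _ranks(x), _ranks(y)
    rho = residual_corr(rx, ry)
    df = n - 2 - c
    if method == "t":
        if df < 1:
            raise FcdPipeError("not enough degrees of freedom for the t approximation")
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt(df / (1 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df))
    elif method == "permutation":
        if n > 8:
            raise FcdPipeError("exact permutation p limited to n <= 8")
        count = 0
        total = 0
        for perm in permutations(range(n)):
            total += 1
            if abs(residual_corr(rx[list(perm)], ry)) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        raise FcdPipeError("method must be 't' or 'permutation'")
    return rho, p


def bonferroni_cutoff(alpha: float = 0.05, n_regions: int = 1) -> float:
    """Per-test cutoff alpha / n_regions."""
    if n_regions < 1:
        raise FcdPipeError("n_regions must be >= 1")
    return alpha / n_regions


@dataclass(frozen=True)
class CorrelationDecision:
    """Significance call for one region-variable correlation."""

    rho: float
    p: float
    cutoff: float
    uncorrected_significant: bool
    bonferroni_significant: bool


def classify_correlation(
    rho: float, p: float, alpha: float = 0.05, n_regions: int = 1
) -> CorrelationDecision:
    """Apply the reporting rule: significant uncorrected iff p < alpha,
    significant after correction iff p < alpha / n_regions."""
    cutoff = bonferroni_cutoff(alpha, n_regions)
    return CorrelationDecision(
        rho=rho, p=p, cutoff=cutoff,
        uncorrected_significant=bool(p < alpha),
        bonferroni_significant=bool(p < cutoff),
    )


def correlation_report(
    region_means: pd.DataFrame,
    clinical: pd.DataFrame,
    variables,
    covariates=None,
    alpha: float = 0.05,
    n_regions: int | None = None,
) -> pd.DataFrame:
    """Partial Spearman of every region mean against every clinical
    variable, with Bonferroni flags.

    ``n_regions`` defaults to the number of region columns (the number of
    regions where altered FCD was detected).
    """
    region_cols = [c for c in region_means.columns if c.startswith("region_")]
    if n_regions is None:
        n_regions = len(region_cols)
    cutoff = bonferroni_cutoff(alpha, n_regions)
    rows = []
    for rc in region_cols:
        for var in variables:
            vals = clinical[var].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() < 4:
                continue
            cov = covariates.loc[ok] if covariates is not None else None
            rho, p = partial_spearman(
                region_means[rc].to_numpy()[ok], vals[ok], covariates=cov
            )
            rows.append({
                "region": rc, "variable": var, "rho": rho, "p_uncorrected": p,
                "cutoff": cutoff,
                "uncorrected_significant": p < alpha,
                "bonferroni_significant": p < cutoff,
            })
    return pd.DataFrame(
        rows, columns=["region", "variable", "rho", "p_uncorrected", "cutoff",
                       "uncorrected_significant", "bonferroni_significant"],
    )
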