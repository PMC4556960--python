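"""Demographic and neuropsychological cohort-table statistics.

Reproduces the standard clinical-table comparisons: Pearson chi-square
(no continuity correction) for the sex distribution and pooled-variance
two-sample t tests for continuous variables, from either raw values or
published mean/SD/n summaries.  Display rounding follows the usual
convention: two decimals, "<0.001" below threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .images import FcdPipeError


@dataclass(frozen=True)
class SummaryStats:
    """Mean, SD and n of one group's variable."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise FcdPipeError("sd must be positive")
        if self.n < 2:
            raise FcdPipeError("n must be >= 2")


def summarize(values) -> SummaryStats:
    x = np.asarray(values, float)
    return SummaryStats(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=len(x))


def chi_square_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square (df = 1, no continuity correction) for the table
    [[a, b], [c, d]].  Returns (chi2, p)."""
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any():
        raise FcdPipeError("counts must be nonnegative")
    if (counts.sum(0) == 0).any() or (counts.sum(1) == 0).any():
        raise FcdPipeError("all table margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), float(p)


def two_sample_t_summary(g1: SummaryStats, g2: SummaryStats, welch: bool = False):
    """Two-sample t from summary statistics.  Pooled-variance (Student) by
    default with df = n1 + n2 - 2; Welch via flag.  Returns (t, df, p)."""
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=not welch,
    )
    if welch:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    else:
        df = g1.n + g2.n - 2
    return float(res.statistic), float(df), float(res.pvalue)


def two_sample_t_raw(x, y, welch: bool = False):
    """Raw-data twin of :func:`two_sample_t_summary` (exactly equal to the
    summary version applied to the computed group summaries)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise FcdPipeError("each group needs n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise FcdPipeError("zero pooled variance; t undefined")
    return two_sample_t_summary(summarize(x), summarize(y), welch=welch)


def format_p(p: float) -> str:
    """Display rounding: '<0.001' below threshold, else two decimals."""
    return "<0.001" if p < 0.001 else f"{p:.2f}"


def build_table1(records) -> pd.DataFrame:
    """Group-comparison table (healthy controls vs all cirrhotic patients).

    ``records`` may be a list of SubjectRecord or a phenotype DataFrame with
    columns group/age/sex/education/nct_a/dst/ammonia.  Emits mean +/- SD
    (or counts) per cohort and the chi-square / t-test p value, rounded for
    display; raw p values are kept in a separate column.
    """
    if not isinstance(records, pd.DataFrame):
        from .synth import Cohort  # noqa: F401  (records of a Cohort)

        records = pd.DataFrame([
            {
                "group": r.group, "age": r.age_y, "sex": r.sex,
                "education": r.education_y, "nct_a": r.nct_a_s, "dst": r.dst_score,
                "ammonia": r.ammonia_umol_l if r.ammonia_umol_l is not None else np.nan,
            }
            for r in records
        ])
    hc = records[records["group"] == "control"]
    pt = records[records["group"] != "control"]
    if len(hc) == 0 or len(pt) == 0:
        raise FcdPipeError("both cohorts (controls and patients) must be nonempty")

    rows = []
    a, b = int((hc["sex"] == "M").sum()), int((hc["sex"] == "F").sum())
    c, d = int((pt["sex"] == "M").sum()), int((pt["sex"] == "F").sum())
    _, p_sex = chi_square_2x2(a, b, c, d)
    rows.append({
        "variable": "Gender (M/F)", "controls": f"{a}/{b}", "patients": f"{c}/{d}",
        "p_value": format_p(p_sex), "p_raw": p_sex, "test": "chi-square",
    })
    for var, label in [("age", "Age (y)"), ("education", "Education (y)"),
                       ("nct_a", "NCT-A (s)"), ("dst", "DST (score)")]:
        t, _, p = two_sample_t_raw(hc[var], pt[var])
        rows.append({
            "variable": label,
            "controls": f"{hc[var].mean():.2f} ± {hc[var].std(ddof=1):.2f}",
            "patients": f"{pt[var].mean():.2f} ± {pt[var].std(ddof=1):.2f}",
            "p_value": format_p(p), "p_raw": p, "test": "two-sample t",
        })
    amm = pt["ammonia"].dropna()
    if len(amm):
        rows.append({
            "variable": "Ammonia (umol/L)", "controls": "",
            "patients": f"{amm.mean():.2f} ± {amm.std(ddof=1):.2f}",
            "p_value": "", "p_raw": np.nan, "test": "",
        })
    return pd.DataFrame(rows)
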