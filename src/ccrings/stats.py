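"""Cohort statistics: normality screening, paired Friedman tests, ICC.

The study compares CC metrics between the pre-treatment visit (T1) and the
visit after the anti-VEGF loading phase (T2). Because the CC variables are
not normally distributed (Shapiro-Wilk screen), visits are compared with the
nonparametric Friedman test per ring and metric; significance is P < 0.05,
with no multiple-testing correction by default (a Holm option exists). The
Friedman statistic is computed with within-eye midranks and the standard tie
correction, and referred to the chi-square distribution with (visits - 1)
degrees of freedom. Inter-grader agreement on lesion areas uses the two-way
mixed-effects, single-rater, consistency ICC -- ICC(3,1) -- with an F-based
95% confidence interval.

Note scipy's Friedman routine requires at least three treatments; with two
visits the statistic is computed here directly (same midrank/tie-correction
formulation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedCohortTable",
    "ComparisonResult",
    "IccResult",
    "shapiro_normality",
    "friedman_statistic",
    "friedman_compare",
    "icc_two_way",
    "cohort_summary",
    "holm_adjust",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedCohortTable:
    """n_eyes x n_visits block of one metric in one ring.

    Rows with any missing cell (flagged rings) are dropped pairwise at
    construction; the drop count is logged.
    """

    values: np.ndarray
    metric: str = ""
    ring: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("paired table must be 2-D (eyes x visits)")
        keep = ~np.isnan(vals).any(axis=1)
        dropped = int((~keep).sum())
        if dropped:
            log.info(
                "%s ring %d: dropped %d eye(s) with flagged/missing cells",
                self.metric, self.ring, dropped,
            )
        object.__setattr__(self, "values", vals[keep])

    @property
    def n_eyes(self) -> int:
        return self.values.shape[0]

    @property
    def n_visits(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ComparisonResult:
    mean_t1: float
    sd_t1: float
    mean_t2: float
    sd_t2: float
    friedman_chi2: float
    df: int
    p_value: float
    n_used: int


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way mixed-effects, consistency, single rater (ICC(3,1))"


def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro-Wilk W and p for one variable (3 <= n <= 5000, non-constant).

    Callers route to the nonparametric comparison when p < 0.05.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample")
    if not 3 <= len(x) <= 5000:
        raise ValueError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality is undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _midranks(row: np.ndarray) -> np.ndarray:
    return sps.rankdata(row, method="average")


def friedman_statistic(values: np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Friedman chi-square on an (eyes x visits) matrix.

    Within-eye midranks; statistic
    chi2 = [12/(n k (k+1)) * sum_j R_j^2 - 3 n (k+1)] / C with the usual tie
    correction C = 1 - sum(t^3 - t) / (n k (k^2 - 1)). Returns
    (chi2, df, p). If every row is fully tied, C = 0 and the statistic is 0
    with p = 1.
    """
    vals = np.asarray(values, dtype=float)
    n, k = vals.shape
    if n < 2 or k < 2:
        raise ValueError("Friedman test needs >= 2 eyes and >= 2 visits")
    ranks = np.apply_along_axis(_midranks, 1, vals)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float((rank_sums**2).sum()) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in vals:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    df = k - 1
    if c <= 0:  # every row fully tied
        return 0.0, df, 1.0
    chi2 /= c
    chi2 = max(chi2, 0.0)
    p = float(sps.chi2.sf(chi2, df))
    return float(chi2), df, p


def friedman_compare(table: PairedCohortTable) -> ComparisonResult:
    """Friedman comparison of one metric across visits, with per-visit
    mean +/- SD attached (first and last visit reported as T1/T2)."""
    vals = table.values
    chi2, df, p = friedman_statistic(vals)
    return ComparisonResult(
        mean_t1=float(vals[:, 0].mean()),
        sd_t1=float(vals[:, 0].std(ddof=1)),
        mean_t2=float(vals[:, -1].mean()),
        sd_t2=float(vals[:, -1].std(ddof=1)),
        friedman_chi2=chi2,
        df=df,
        p_value=p,
        n_used=table.n_eyes,
    )


def icc_two_way(grader_a, grader_b, alpha: float = 0.05) -> IccResult:
    """ICC(3,1): two-way mixed-effects, consistency, single rater, for two
    graders measuring the same subjects.

    ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error) from the
    two-way ANOVA mean squares, with the F-based (1 - alpha) CI. Zero
    between-subject variance leaves the ICC undefined and raises.
    """
    a = np.asarray(grader_a, dtype=float)
    b = np.asarray(grader_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("graders must supply equal-length 1-D measurements")
    n = len(a)
    if n < 5:
        raise ValueError("ICC needs at least 5 subjects")
    k = 2
    data = np.column_stack([a, b])
    subject_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    grand = data.mean()
    ss_subjects = k * float(((subject_means - grand) ** 2).sum())
    ss_raters = n * float(((rater_means - grand) ** 2).sum())
    ss_total = float(((data - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_raters
    ms_subjects = ss_subjects / (n - 1)
    ms_error = ss_error / ((n - 1) * (k - 1))
    if ms_subjects <= 0 or (ms_subjects == 0 and ms_error == 0):
        raise ValueError("zero between-subject variance: ICC undefined")
    if ms_error == 0:
        return IccResult(1.0, 1.0, 1.0)
    icc = (ms_subjects - ms_error) / (ms_subjects + (k - 1) * ms_error)
    f_obs = ms_subjects / ms_error
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_l = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_l - 1) / (f_l + k - 1)
    ci_high = (f_u - 1) / (f_u + k - 1)
    return IccResult(float(icc), float(ci_low), float(ci_high))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; the default analysis
    reports unadjusted per-ring tests)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


_METRIC_COLUMNS = {
    "fd_percent": "FD%",
    "fd_avg_area_um2": "FDa (um^2)",
    "fd_count": "FDn",
}


def cohort_summary(
    per_eye_metrics: dict[str, dict[str, "object"]],
    holm: bool = False,
) -> dict[str, pd.DataFrame]:
    """Summarize a paired cohort into per-metric tables.

    Parameters
    ----------
    per_eye_metrics
        Mapping ``eye_id -> {"t1": RingMetrics, "t2": RingMetrics}``.
    holm
        If True, add Holm-adjusted p-values per metric family.

    Returns
    -------
    dict
        One DataFrame per metric (rows R1..Rn: mean +/- SD at T1 and T2,
        Friedman chi2 and p, n used, Shapiro p of the pooled values) plus a
        ``"lesion_areas"`` table comparing MNV and dark-halo areas between
        visits.
    """
    eyes = sorted(per_eye_metrics)
    if len(eyes) < 2:
        raise ValueError("cohort summary needs >= 2 eyes")
    first = per_eye_metrics[eyes[0]]["t1"]
    n_rings = len(first.rings)  # type: ignore[attr-defined]
    out: dict[str, pd.DataFrame] = {}
    for attr, label in _METRIC_COLUMNS.items():
        rows = []
        p_list = []
        for ring in range(n_rings):
            t1_vals, t2_vals = [], []
            for eye in eyes:
                m1 = per_eye_metrics[eye]["t1"].metric_array(attr)[ring]  # type: ignore[attr-defined]
                m2 = per_eye_metrics[eye]["t2"].metric_array(attr)[ring]  # type: ignore[attr-defined]
                t1_vals.append(m1)
                t2_vals.append(m2)
            table = PairedCohortTable(
                np.column_stack([t1_vals, t2_vals]), metric=label, ring=ring + 1
            )
            res = friedman_compare(table)
            pooled = np.concatenate([table.values[:, 0], table.values[:, 1]])
            try:
                _, shapiro_p = shapiro_normality(pooled)
            except ValueError:
                shapiro_p = float("nan")
            rows.append(
                {
                    "ring": f"R{ring + 1}",
                    "mean_t1": res.mean_t1,
                    "sd_t1": res.sd_t1,
                    "mean_t2": res.mean_t2,
                    "sd_t2": res.sd_t2,
                    "friedman_chi2": res.friedman_chi2,
                    "df": res.df,
                    "p_value": res.p_value,
                    "n_used": res.n_used,
                    "shapiro_p": shapiro_p,
                }
            )
            p_list.append(res.p_value)
        df = pd.DataFrame(rows).set_index("ring")
        if holm:
            df["p_holm"] = holm_adjust(p_list)
        out[attr] = df

    area_rows = []
    for name, attr in (("MNV area (mm^2)", "mnv_area_mm2"), ("DH area (mm^2)", "dh_area_mm2")):
        t1_vals = np.array([getattr(per_eye_metrics[e]["t1"], attr) for e in eyes], dtype=float)
        t2_vals = np.array([getattr(per_eye_metrics[e]["t2"], attr) for e in eyes], dtype=float)
        table = PairedCohortTable(np.column_stack([t1_vals, t2_vals]), metric=name)
        res = friedman_compare(table)
        area_rows.append(
            {
                "variable": name,
                "mean_t1": res.mean_t1,
                "sd_t1": res.sd_t1,
                "mean_t2": res.mean_t2,
                "sd_t2": res.sd_t2,
                "friedman_chi2": res.friedman_chi2,
                "p_value": res.p_value,
                "n_used": res.n_used,
            }
        )
    out["lesion_areas"] = pd.DataFrame(area_rows).set_index("variable")
    return out
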