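"""Long-term test-retest reliability statistics.

A measurement series is a subjects x sessions table (missing cells
allowed).  The suite computes, per series: the intraclass correlation
ICC(1,1) from one-way random-effects ANOVA with an exact F-based 95% CI;
the standard error of measurement SEM = SD * sqrt(1 - ICC); the minimum
detectable difference MD = SEM * sqrt(2) * 1.96 (and MD% = 100 * MD /
mean); the within-subject coefficient of variation with a chi-square CI;
Bland-Altman agreement of every follow-up session against baseline with
linear-bias regression and Benjamini-Hochberg FDR control; and
between-session Pearson correlation matrices.

Unbalanced designs use the standard one-way correction, replacing the
common replicate count k with k0 = (N - sum(k_i^2)/N) / (n - 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReliabilityMetrics",
    "BlandAltmanResult",
    "icc_1_1",
    "sem_from_sd_icc",
    "minimum_detectable_difference",
    "md_percent",
    "sem_md_confidence_intervals",
    "coefficient_of_variation",
    "bland_altman",
    "fdr_adjust",
    "correlation_matrix",
    "classify_icc",
    "reliability_metrics",
    "reliability_table",
    "average_levels",
]

MD_FACTOR = math.sqrt(2.0) * 1.96  # = 2.7719; MD per unit SEM


def _as_matrix(series) -> np.ndarray:
    m = series.to_numpy(dtype=float) if isinstance(series, pd.DataFrame) else np.asarray(series, dtype=float)
    if m.ndim != 2:
        raise ValueError("measurement series must be a 2-D subjects x sessions table")
    return m


def _anova_sums(m: np.ndarray):
    counts = np.sum(~np.isnan(m), axis=1)
    keep = counts >= 1
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} subject(s) with no observations")
    m = m[keep]
    counts = counts[keep]
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects with observations")
    big_n = int(counts.sum())
    if big_n <= n:
        raise ValueError("need replicate sessions to separate variance components")
    grand = np.nansum(m) / big_n
    subj_means = np.nanmean(m, axis=1)
    bss = float(np.sum(counts * (subj_means - grand) ** 2))
    wss = float(np.nansum((m - subj_means[:, None]) ** 2))
    bms = bss / (n - 1)
    wms = wss / (big_n - n)
    k0 = (big_n - float(np.sum(counts**2)) / big_n) / (n - 1)
    return n, big_n, bms, wms, k0


def icc_1_1(series, alpha: float = 0.05) -> tuple[float, float, float]:
    """ICC(1,1): one-way random-effects, single measurement.

    ICC = (BMS - WMS) / (BMS + (k0 - 1) WMS), with the exact F-based
    confidence interval.  All available observations of an unbalanced table
    are used.
    """
    n, big_n, bms, wms, k0 = _anova_sums(_as_matrix(series))
    if wms == 0:
        icc = 1.0 if bms > 0 else 0.0
        return icc, icc, icc
    icc = (bms - wms) / (bms + (k0 - 1.0) * wms)
    f_obs = bms / wms
    df1, df2 = n - 1, big_n - n
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    lo = (fl - 1.0) / (fl + k0 - 1.0)
    hi = (fu - 1.0) / (fu + k0 - 1.0)
    return float(icc), float(lo), float(hi)


def sem_from_sd_icc(sd: float, icc: float) -> float:
    """SEM = SD of the sample scores * sqrt(1 - ICC).

    A negative ICC estimate is clamped to 0 here (SEM cannot exceed the
    observed SD), with a warning.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if icc < 0:
        warnings.warn("negative ICC clamped to 0 inside the SEM formula")
        icc = 0.0
    return float(sd * math.sqrt(1.0 - min(icc, 1.0)))


def minimum_detectable_difference(sem: float) -> float:
    """MD (a.k.a. MDC): SEM * sqrt(2) * 1.96."""
    if sem < 0:
        raise ValueError("sem must be >= 0")
    return float(sem * MD_FACTOR)


def md_percent(md: float, mean: float) -> float:
    """MD as a percentage of the series mean."""
    if mean <= 0:
        raise ValueError("mean must be > 0 for MD%")
    return float(100.0 * md / mean)


def sem_md_confidence_intervals(sd: float, icc_ci: tuple[float, float]):
    """Propagate the ICC confidence bounds through the SEM and MD formulas.

    The upper ICC bound gives the lower SEM bound and vice versa; MD bounds
    are the SEM bounds times sqrt(2)*1.96.
    """
    lo_icc, hi_icc = icc_ci
    sem_ci = (sem_from_sd_icc(sd, hi_icc), sem_from_sd_icc(sd, max(lo_icc, 0.0)))
    return sem_ci, (sem_ci[0] * MD_FACTOR, sem_ci[1] * MD_FACTOR)


def coefficient_of_variation(series, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Within-subject CV (percent) with a chi-square confidence interval.

    Per subject with >=2 sessions, CV_i = SD_i / mean_i; the reported CV is
    the root-mean-square over subjects, and the CI scales it by the
    chi-square quantiles of the pooled within-subject variance with
    sum(k_i - 1) degrees of freedom.
    """
    m = _as_matrix(series)
    if np.nanmin(m) <= 0:
        raise ValueError("CV requires strictly positive measurements")
    counts = np.sum(~np.isnan(m), axis=1)
    usable = counts >= 2
    if (~usable & (counts > 0)).any():
        warnings.warn("subjects with a single session are excluded from the CV")
    if not usable.any():
        raise ValueError("no subject has >= 2 sessions")
    sub = m[usable]
    k = counts[usable]
    cv_i = np.nanstd(sub, axis=1, ddof=1) / np.nanmean(sub, axis=1)
    cv = 100.0 * float(np.sqrt(np.mean(cv_i**2)))
    df = int(np.sum(k - 1))
    lo = cv * math.sqrt(df / stats.chi2.ppf(1 - alpha / 2, df))
    hi = cv * math.sqrt(df / stats.chi2.ppf(alpha / 2, df))
    return cv, (float(lo), float(hi))


@dataclass
class BlandAltmanResult:
    """Agreement of one follow-up session against the reference session."""

    reference: object
    session: object
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_slope: float
    bias_p: float
    fdr_p: float = float("nan")
    insufficient: bool = False
    pair_means: np.ndarray | None = None
    pair_diffs: np.ndarray | None = None


def bland_altman(series: pd.DataFrame, reference_session=None) -> list[BlandAltmanResult]:
    """Bland-Altman agreement of each follow-up session vs the reference.

    Differences are follow-up minus reference on subjects present in both;
    limits of agreement are mean +- 1.96 SD of the differences, and linear
    bias is the OLS slope of difference on pair mean.  FDR-adjusted p-values
    (Benjamini-Hochberg over the returned comparisons) are filled in.
    """
    if not isinstance(series, pd.DataFrame):
        series = pd.DataFrame(np.asarray(series, dtype=float))
    if reference_session is None:
        reference_session = series.columns[0]
    if reference_session not in series.columns:
        raise ValueError(f"reference session {reference_session!r} not in series")
    ref = series[reference_session]
    out: list[BlandAltmanResult] = []
    for col in series.columns:
        if col == reference_session:
            continue
        pair = pd.concat([ref, series[col]], axis=1).dropna()
        n = len(pair)
        if n < 3:
            out.append(BlandAltmanResult(reference_session, col, n, *(float("nan"),) * 6,
                                         insufficient=True))
            continue
        a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
        diffs = b - a
        means = 0.5 * (a + b)
        md, sd = float(diffs.mean()), float(diffs.std(ddof=1))
        if np.allclose(means, means[0]) or sd == 0:
            slope, p = 0.0, 1.0
        else:
            reg = stats.linregress(means, diffs)
            slope, p = float(reg.slope), float(reg.pvalue)
        out.append(
            BlandAltmanResult(
                reference=reference_session, session=col, n=n, mean_diff=md, sd_diff=sd,
                loa_low=md - 1.96 * sd, loa_high=md + 1.96 * sd,
                bias_slope=slope, bias_p=p, pair_means=means, pair_diffs=diffs,
            )
        )
    valid = [r for r in out if not r.insufficient]
    if valid:
        adj = fdr_adjust([r.bias_p for r in valid])
        for r, p in zip(valid, adj):
            r.fdr_p = float(p)
    return out


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def correlation_matrix(series: pd.DataFrame, min_subjects: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson r between sessions; cells with fewer than
    ``min_subjects`` common subjects are NaN."""
    if not isinstance(series, pd.DataFrame):
        series = pd.DataFrame(np.asarray(series, dtype=float))
    return series.corr(method="pearson", min_periods=min_subjects)


def two_triangle_matrix(upper: pd.DataFrame, lower: pd.DataFrame) -> pd.DataFrame:
    """Combine two session correlation matrices into one table: ``upper``
    above the diagonal, ``lower`` below (the whole-disc / nucleus layout)."""
    out = upper.copy().astype(float)
    n = out.shape[0]
    for i in range(n):
        out.iloc[i, i] = np.nan
        for j in range(i):
            out.iloc[i, j] = lower.iloc[i, j]
    return out


def classify_icc(icc: float) -> str:
    """Reliability label: <0.40 poor, 0.40-0.59 moderate, 0.60-0.74 good,
    >=0.75 excellent."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "moderate"
    if icc < 0.75:
        return "good"
    return "excellent"


@dataclass
class ReliabilityMetrics:
    """One reliability-table row."""

    measure: str
    mean: float
    sd: float
    icc: float
    icc_ci: tuple[float, float]
    sem: float
    sem_ci: tuple[float, float]
    md: float
    md_ci: tuple[float, float]
    md_pct: float
    cv: float
    cv_ci: tuple[float, float]
    classification: str
    n_subjects: int


def reliability_metrics(series: pd.DataFrame, measure: str = "", alpha: float = 0.05) -> ReliabilityMetrics:
    """Full metric set for one subjects x sessions series."""
    m = _as_matrix(series)
    vals = m[~np.isnan(m)]
    mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    icc, lo, hi = icc_1_1(series, alpha=alpha)
    sem = sem_from_sd_icc(sd, icc)
    md = minimum_detectable_difference(sem)
    sem_ci, md_ci = sem_md_confidence_intervals(sd, (lo, hi))
    cv, cv_ci = coefficient_of_variation(series, alpha=alpha)
    return ReliabilityMetrics(
        measure=measure, mean=mean, sd=sd, icc=icc, icc_ci=(lo, hi),
        sem=sem, sem_ci=sem_ci, md=md, md_ci=md_ci,
        md_pct=md_percent(md, mean), cv=cv, cv_ci=cv_ci,
        classification=classify_icc(icc),
        n_subjects=int(np.sum(np.any(~np.isnan(m), axis=1))),
    )


def average_levels(level_series: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-subject per-session mean over vertebral levels (the "AvLx" row)."""
    frames = list(level_series.values())
    stacked = pd.concat(frames, keys=range(len(frames)))
    return stacked.groupby(level=1).mean()


def reliability_table(all_series: dict[str, pd.DataFrame], grades: dict[str, int] | None = None,
                      grade_series: dict[int, pd.DataFrame] | None = None,
                      avlx: bool = True, alpha: float = 0.05) -> pd.DataFrame:
    """Assemble a reliability table: one row per measure, an averaged-levels
    row when requested, and optional grade-stratified rows.

    ``all_series`` maps measure names (e.g. ``"whole L4/5"``) to series;
    ``grade_series`` maps a degeneration grade to a pooled series whose rows
    are (subject, disc) units of that grade.
    """
    rows: list[ReliabilityMetrics] = []
    if avlx and len(all_series) > 1:
        rows.append(reliability_metrics(average_levels(all_series), measure="AvLx", alpha=alpha))
    for name, series in all_series.items():
        rows.append(reliability_metrics(series, measure=name, alpha=alpha))
    if grade_series:
        for grade in sorted(grade_series):
            rows.append(reliability_metrics(grade_series[grade], measure=f"Grade {grade}", alpha=alpha))
    records = []
    for r in rows:
        records.append(
            {
                "measure": r.measure,
                "mean": r.mean, "sd": r.sd,
                "icc": r.icc, "icc_lo": r.icc_ci[0], "icc_hi": r.icc_ci[1],
                "sem": r.sem, "sem_lo": r.sem_ci[0], "sem_hi": r.sem_ci[1],
                "md": r.md, "md_lo": r.md_ci[0], "md_hi": r.md_ci[1],
                "md_pct": r.md_pct,
                "cv": r.cv, "cv_lo": r.cv_ci[0], "cv_hi": r.cv_ci[1],
                "classification": r.classification,
                "n_subjects": r.n_subjects,
            }
        )
    return pd.DataFrame(records)
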