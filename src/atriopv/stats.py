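"""Nonparametric cohort statistics.

Every comparison in the pipeline is nonparametric (a Shapiro-Wilk screen is
advisory only): two-tailed Wilcoxon signed-rank for paired contrasts,
Mann-Whitney-Wilcoxon for unpaired ones, percentile-bootstrap confidence
intervals for medians and median differences, Bonferroni gating for
families of comparisons, Spearman rank correlations, and single-measure
intraclass correlations for reproducibility.

Exactness policy: the signed-rank null is evaluated exactly (full sign
distribution) for n <= 25 tie-free samples, Mann-Whitney exactly for
n1 + n2 <= 16 tie-free samples, and Spearman p by full permutation for
n <= 10; larger or tied samples use the tie-corrected normal / t
approximations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

from .io import RHYTHMS, ValidationError

WILCOXON_EXACT_N = 25
MANN_WHITNEY_EXACT_N = 16
SPEARMAN_EXACT_N = 10
DEFAULT_RESAMPLES = 10_000


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str  # "wilcoxon_signed_rank" | "mann_whitney"
    estimate: float  # median difference (paired) / difference of medians
    medians: tuple[float, ...]  # (median diff,) or (median_a, median_b)
    ci: tuple[float, float]
    ci_level: float  # %
    n2: int | None = None


@dataclass
class CorrelationResult:
    rs: float
    p_value: float
    n: int


@dataclass
class ICCResult:
    icc: float
    ci: tuple[float, float]
    model: str  # "icc21" | "icc31"
    n_subjects: int
    n_ratings: int


@dataclass
class CohortSplit:
    variable: str
    threshold: float
    low_ids: list
    high_ids: list
    low_bounds: tuple[float, float]
    high_bounds: tuple[float, float]


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality screen (advisory; the pipeline always
    proceeds nonparametrically)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValidationError("Shapiro-Wilk needs n >= 3")
    if x.size > 5000:
        raise ValidationError("Shapiro-Wilk valid only for n <= 5000")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate sample: zero variance")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def bootstrap_ci(
    data,
    statistic=None,
    level_pct: float = 95.0,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a statistic (default: median).

    ``data`` may be a single sample or a tuple of two independent samples;
    in the latter case the default statistic is the difference of medians
    and each group is resampled independently.  Reproducible given
    ``seed``.
    """
    if not 50 < level_pct < 100:
        raise ValidationError("level_pct must be in (50, 100)")
    if n_resamples < 1000:
        raise ValidationError("n_resamples must be >= 1000")
    rng = np.random.default_rng(seed)
    alpha = (100.0 - level_pct) / 2.0
    two_sample = isinstance(data, tuple)
    if not two_sample:
        x = np.asarray(data, dtype=float)
        if x.size < 5:
            raise ValidationError("bootstrap needs n >= 5")
        if statistic is None or statistic is np.median:
            # vectorized fast path for the default
            idx = rng.integers(0, x.size, size=(n_resamples, x.size))
            stats = np.median(x[idx], axis=1)
        else:
            stats = np.array(
                [statistic(x[rng.integers(0, x.size, x.size)]) for _ in range(n_resamples)]
            )
    else:
        a = np.asarray(data[0], dtype=float)
        b = np.asarray(data[1], dtype=float)
        if a.size < 5 or b.size < 5:
            raise ValidationError("bootstrap needs n >= 5 in each group")
        if statistic is None:
            ia = rng.integers(0, a.size, size=(n_resamples, a.size))
            ib = rng.integers(0, b.size, size=(n_resamples, b.size))
            stats = np.median(a[ia], axis=1) - np.median(b[ib], axis=1)
        else:
            stats = np.array(
                [
                    statistic(a[rng.integers(0, a.size, a.size)], b[rng.integers(0, b.size, b.size)])
                    for _ in range(n_resamples)
                ]
            )
    lo, hi = np.percentile(stats, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def wilcoxon_signed_rank(
    paired_diffs,
    ci_level: float = 95.0,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | None = None,
    zero_method: str = "wilcox",
) -> TestResult:
    """Two-tailed Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon's original treatment;
    ``zero_method="pratt"`` keeps them in the ranking).  The point
    estimate is the median difference with a percentile-bootstrap CI.
    """
    d = np.asarray(paired_diffs, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise ValidationError("all paired differences are zero")
    if nonzero.size < 5:
        raise ValidationError("need >= 5 nonzero paired differences")
    n = nonzero.size
    has_ties = np.unique(np.abs(nonzero)).size < n
    method = "exact" if (n <= WILCOXON_EXACT_N and not has_ties and zero_method == "wilcox") else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, zero_method=zero_method, alternative="two-sided", method=method)
    est = float(np.median(d))
    ci = bootstrap_ci(d, level_pct=ci_level, n_resamples=n_resamples, seed=seed)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        method="wilcoxon_signed_rank",
        estimate=est,
        medians=(est,),
        ci=ci,
        ci_level=ci_level,
    )


def mann_whitney(
    group_a,
    group_b,
    ci_level: float = 95.0,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | None = None,
) -> TestResult:
    """Two-tailed Mann-Whitney-Wilcoxon test on two independent groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValidationError("each group needs n >= 3")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= MANN_WHITNEY_EXACT_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if min(a.size, b.size) >= 5:
        ci = bootstrap_ci((a, b), level_pct=ci_level, n_resamples=n_resamples, seed=seed)
    else:  # groups too small to resample meaningfully
        ci = (float("nan"), float("nan"))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=a.size,
        n2=b.size,
        method="mann_whitney",
        estimate=med_a - med_b,
        medians=(med_a, med_b),
        ci=ci,
        ci_level=ci_level,
    )


def bonferroni_gate(p_values, family_size: int, alpha: float = 0.05):
    """Significance flags at the Bonferroni-corrected threshold alpha/m.

    For the four paired volume time-point pairings this gives the
    P < 0.0125 threshold (with 98.75% CIs elsewhere in the pipeline).
    """
    if family_size < 1:
        raise ValidationError("family_size must be >= 1")
    threshold = alpha / family_size
    flags = np.asarray(p_values, dtype=float) < threshold
    return flags, threshold


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rs_obs: float) -> float:
    """Two-tailed permutation p for Spearman rs by full enumeration."""
    n = rx.size
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt(np.sum(rx_c**2) * np.sum(ry_c**2))
    count = total = 0
    chunk: list = []
    target = abs(rs_obs) - 1e-12

    def flush(chunk_perms):
        nonlocal count, total
        perms = np.array(chunk_perms)
        rs = (perms @ rx_c) / denom
        count += int(np.sum(np.abs(rs) >= target))
        total += perms.shape[0]

    for perm in itertools.permutations(ry_c):
        chunk.append(perm)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return count / total


def spearman(x, y, exact_n_max: int = SPEARMAN_EXACT_N) -> CorrelationResult:
    """Spearman rank correlation with ties handled by mid-ranks.

    The p-value is exact by full permutation for n <= ``exact_n_max`` and
    uses the t-approximation otherwise; two-tailed throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x/y length mismatch")
    if x.size < 5:
        raise ValidationError("Spearman needs n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in ranks")
    rs, p = sps.spearmanr(x, y)
    rs = float(rs)
    if x.size <= exact_n_max:
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        p = _exact_spearman_p(rx, ry, rs)
    return CorrelationResult(rs=rs, p_value=float(p), n=x.size)


def median_split(cohort: pd.DataFrame, variable: str) -> CohortSplit:
    """Split the cohort into halves about the median of ``variable``.

    The middle patient of an odd-sized cohort goes to the lower group.
    Ties spanning the boundary are resolved deterministically by
    patient_id order, with a warning.
    """
    if variable not in cohort.columns:
        raise ValidationError(f"variable {variable!r} not in cohort table")
    if cohort[variable].isna().any():
        raise ValidationError(f"variable {variable!r} missing for some patients")
    ordered = cohort.sort_values([variable, "patient_id"], kind="mergesort")
    n = len(ordered)
    n_low = (n + 1) // 2
    vals = ordered[variable].to_numpy(float)
    if n_low < n and vals[n_low - 1] == vals[n_low]:
        warnings.warn(
            f"ties span the median boundary of {variable!r}; "
            "resolved by patient_id order",
            stacklevel=2,
        )
    low = ordered.iloc[:n_low]
    high = ordered.iloc[n_low:]
    return CohortSplit(
        variable=variable,
        threshold=float(np.median(vals)),
        low_ids=list(low["patient_id"]),
        high_ids=list(high["patient_id"]),
        low_bounds=(float(vals[0]), float(vals[n_low - 1])),
        high_bounds=(float(vals[n_low]), float(vals[-1])),
    )


def icc(ratings_matrix, model: str = "icc21", ci_level: float = 95.0) -> ICCResult:
    """Single-measure intraclass correlation from two-way ANOVA mean squares.

    ``model="icc21"`` is the two-way random-effects absolute-agreement
    form ICC(2,1) (interobserver); ``model="icc31"`` the two-way
    mixed-effects single-rater form ICC(3,1) (intraobserver).  Confidence
    intervals use the standard F-distribution formulas.
    """
    if model not in ("icc21", "icc31"):
        raise ValidationError(f"unknown ICC model {model!r}")
    x = np.asarray(ratings_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValidationError("ratings matrix must be (n_subjects, 2)")
    n, k = x.shape
    if n < 5:
        raise ValidationError("ICC needs >= 5 subjects")
    if not np.all(np.isfinite(x)):
        raise ValidationError("missing cells in ratings matrix")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    alpha = 1 - ci_level / 100.0

    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "icc31":
            denom = msr + (k - 1) * mse
            value = (msr - mse) / denom if denom > 0 else 1.0
            if mse > 0:
                f_obs = msr / mse
                df1, df2 = n - 1, (n - 1) * (k - 1)
                fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
                fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
                ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
            else:
                ci = (value, value)
        else:
            denom = msr + (k - 1) * mse + k * (msc - mse) / n
            value = (msr - mse) / denom if denom > 0 else 1.0
            if mse > 0 or msc > 0:
                a = k * value / (n * (1 - value)) if value < 1 else np.inf
                b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
                num_v = (a * msc + b * mse) ** 2
                den_v = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
                v = num_v / den_v if den_v > 0 else 1.0
                f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
                f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
                lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
                hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
                ci = (lo, hi)
            else:
                ci = (value, value)
    ci = (float(min(ci[0], value)), float(max(ci[1], value)))
    return ICCResult(icc=float(value), ci=ci, model=model, n_subjects=n, n_ratings=k)


# ---------------------------------------------------------------------------
# cohort analysis bundle
# ---------------------------------------------------------------------------

COHORT_ANALYSES = {
    "rhythm": None,  # categorical split
    "lap_mean": "lap_mean_t2",
    "vmax_indexed": "vmax_idx_t1",
    "laad_indexed": "laa_depth_idx",
}


def _group_tests(group: pd.DataFrame, ci_level: float, n_resamples: int, seed) -> dict:
    if len(group) < 5:
        raise ValidationError(f"group size {len(group)} < 5 after split")
    diffs = (group["stiff_t3"] - group["stiff_t2"]).to_numpy(float)
    paired = wilcoxon_signed_rank(diffs, ci_level=ci_level, n_resamples=n_resamples, seed=seed)
    return {
        "n": len(group),
        "stiff_t2_median": float(group["stiff_t2"].median()),
        "stiff_t3_median": float(group["stiff_t3"].median()),
        "delta_median": float(group["delta_stiff"].median()),
        "paired_wilcoxon": paired,
    }


def run_cohort_analysis(
    cohort: pd.DataFrame,
    ci_level: float = 95.0,
    n_resamples: int = DEFAULT_RESAMPLES,
    seed: int | None = None,
) -> dict:
    """Run the four cohort analyses on stiffness plus LAA correlations.

    For each grouping (all patients; presenting rhythm; median split on
    pre-implantation mean LAP; on indexed baseline Vmax; on indexed LAA
    depth) the paired T2-vs-T3 Wilcoxon on stiffness is computed per
    group, with between-group Mann-Whitney tests on stiffness at each
    time point and on the stiffness change.  Spearman correlations of
    stiffness change and post-occlusion stiffness against indexed LAA
    depth and width are attached.
    """
    from .io import validate_cohort_table

    validate_cohort_table(cohort)
    results: dict = {"analyses": {}, "correlations": {}}

    results["analyses"]["all"] = {
        "groups": {"all": _group_tests(cohort, ci_level, n_resamples, seed)}
    }

    for name, variable in COHORT_ANALYSES.items():
        if name == "rhythm":
            groups = {r: cohort[cohort["rhythm"] == r] for r in RHYTHMS}
            labels = dict(zip(RHYTHMS, RHYTHMS))
            bounds = {}
        else:
            split = median_split(cohort, variable)
            groups = {
                "low": cohort[cohort["patient_id"].isin(split.low_ids)],
                "high": cohort[cohort["patient_id"].isin(split.high_ids)],
            }
            labels = {"low": "low", "high": "high"}
            bounds = {"low": split.low_bounds, "high": split.high_bounds}
        entry: dict = {"groups": {}, "between": {}}
        (ka, ga), (kb, gb) = groups.items()
        for key, g in groups.items():
            entry["groups"][labels[key]] = _group_tests(g, ci_level, n_resamples, seed)
            if key in bounds:
                entry["groups"][labels[key]]["bounds"] = bounds[key]
        for col, label in (
            ("stiff_t2", "stiff_t2"),
            ("stiff_t3", "stiff_t3"),
            ("delta_stiff", "delta_stiff"),
        ):
            entry["between"][label] = mann_whitney(
                ga[col].to_numpy(float),
                gb[col].to_numpy(float),
                ci_level=ci_level,
                n_resamples=n_resamples,
                seed=seed,
            )
        results["analyses"][name] = entry

    for target in ("delta_stiff", "stiff_t3"):
        for predictor in ("laa_depth_idx", "laa_width_idx"):
            results["correlations"][f"{target}_vs_{predictor}"] = spearman(
                cohort[predictor].to_numpy(float), cohort[target].to_numpy(float)
            )
    return results


def cohort_results_table(results: dict) -> pd.DataFrame:
    """Flatten a cohort-analysis bundle into a stiffness summary table."""
    rows = []
    for analysis, entry in results["analyses"].items():
        for group, g in entry["groups"].items():
            pw = g["paired_wilcoxon"]
            rows.append(
                {
                    "analysis": analysis,
                    "group": group,
                    "n": g["n"],
                    "stiff_t2_median": g["stiff_t2_median"],
                    "stiff_t3_median": g["stiff_t3_median"],
                    "delta_median": g["delta_median"],
                    "p_wilcoxon": pw.p_value,
                    "ci_lo": pw.ci[0],
                    "ci_hi": pw.ci[1],
                    "p_mww_delta": (
                        entry["between"]["delta_stiff"].p_value if "between" in entry else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)
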