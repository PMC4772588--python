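"""Permutation tests, regression-line comparison and EM correlation analysis.

The two-sample permutation test uses the difference in group means as
its statistic, two-sided via the absolute value.  When the number of
distinct group assignments C(n+m, n) is small enough the null is
enumerated exhaustively and the p value is the exact tail fraction
(including the identity assignment, so p is always in (0, 1]);
otherwise a seeded Monte-Carlo null with the add-one correction
``p = (b + 1) / (B + 1)`` is used.

Destaining rate differences between genotypes are tested by pooling the
post-stimulation RI points of all traces and fitting
``RI ~ time + group + time:group`` by OLS; the F test of the
interaction term(s) asks whether the regression lines have different
slopes.  Intercepts are reported at the stimulation-onset time origin.
An optional per-trace robustness mode permutes per-trace OLS slopes
instead of pooling points.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError
from .io import log_stage

#: largest enumerable number of group assignments for the exhaustive null
MAX_EXHAUSTIVE = 200_000
#: tolerance when comparing permuted statistics against the observed one
_TAIL_EPS = 1e-12


@dataclass
class PermutationTestResult:
    observed_statistic: float
    p_value: float
    n_permutations: int
    exhaustive: bool
    seed: int | None = None


@dataclass
class RegressionComparison:
    """Per-group lines and the slope-difference (interaction) F test."""

    groups: tuple
    intercepts: dict
    slopes: dict
    intercept_se: dict
    slope_se: dict
    f_stat: float
    p_value: float
    df_num: int
    df_resid: int
    n_points: int


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float


# ---------------------------------------------------------------------------
# Permutation t test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _combination_indices(n_total: int, n_x: int) -> np.ndarray:
    """All C(n_total, n_x) index subsets as an int array (cached)."""
    idx = np.fromiter(
        (i for c in combinations(range(n_total), n_x) for i in c),
        dtype=np.intp, count=comb(n_total, n_x) * n_x)
    return idx.reshape(-1, n_x)


def permutation_t_test(x, y, n_permutations: int = 10_000,
                       seed: int | None = None,
                       exhaustive: bool | str = "auto") -> PermutationTestResult:
    """Two-sample permutation test on the difference of means.

    Parameters
    ----------
    x, y
        The two samples (each needs >= 2 values).
    n_permutations
        Monte-Carlo resamples B when the exhaustive null is not used.
    exhaustive
        "auto" enumerates all assignments when C(n+m, n) <=
        ``MAX_EXHAUSTIVE``; True forces enumeration; False forces
        Monte-Carlo.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            f"permutation_t_test: each group needs >= 2 values "
            f"(got {len(x)}, {len(y)})")
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    t_obs = x.mean() - y.mean()
    n_comb = comb(n + m, n)

    use_exhaustive = (exhaustive is True) or \
        (exhaustive == "auto" and n_comb <= MAX_EXHAUSTIVE)
    if use_exhaustive:
        idx = _combination_indices(n + m, n)
        sums = pooled[idx].sum(axis=1)
        total = pooled.sum()
        t_perm = sums / n - (total - sums) / m
        b = int(np.count_nonzero(np.abs(t_perm) >= abs(t_obs) - _TAIL_EPS))
        return PermutationTestResult(float(t_obs), b / n_comb, n_comb,
                                     exhaustive=True)
    rng = np.random.default_rng(seed)
    B = int(n_permutations)
    mat = rng.permuted(np.tile(pooled, (B, 1)), axis=1)
    t_perm = mat[:, :n].mean(axis=1) - mat[:, n:].mean(axis=1)
    b = int(np.count_nonzero(np.abs(t_perm) >= abs(t_obs) - _TAIL_EPS))
    return PermutationTestResult(float(t_obs), (b + 1) / (B + 1), B,
                                 exhaustive=False, seed=seed)


# ---------------------------------------------------------------------------
# Regression-line comparison
# ---------------------------------------------------------------------------

def compare_regression_lines(df: pd.DataFrame) -> RegressionComparison:
    """Pooled OLS ``ri ~ time * group`` with an interaction F test.

    ``df`` must have columns group, time, ri; time should already be
    expressed relative to the chosen origin (stimulation onset).  Works
    for two or more groups; with g groups the interaction F test has
    g - 1 numerator degrees of freedom.
    """
    for col in ("group", "time", "ri"):
        if col not in df.columns:
            raise ValidationError(f"compare_regression_lines: missing column {col!r}")
    groups = tuple(sorted(df["group"].unique()))
    if len(groups) < 2:
        raise ValidationError(
            f"compare_regression_lines: need >= 2 groups, got {groups}")
    time = df["time"].to_numpy(float)
    ri = df["ri"].to_numpy(float)
    cols = [np.ones(len(df)), time]
    names = ["const", "time"]
    for g in groups[1:]:
        ind = (df["group"] == g).to_numpy(float)
        cols += [ind, ind * time]
        names += [f"g[{g}]", f"time:g[{g}]"]
    exog = np.column_stack(cols)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise DegenerateInputError(
            "compare_regression_lines: collinear/degenerate design "
            "(is time constant within a group?)")
    res = sm.OLS(ri, exog).fit()
    k = exog.shape[1]
    inter_idx = [names.index(f"time:g[{g}]") for g in groups[1:]]
    R = np.zeros((len(inter_idx), k))
    for r_i, c_i in enumerate(inter_idx):
        R[r_i, c_i] = 1.0
    ftest = res.f_test(R)
    f_stat = float(np.squeeze(ftest.fvalue))
    p_value = float(ftest.pvalue)

    cov = res.cov_params()
    intercepts, slopes, i_se, s_se = {}, {}, {}, {}
    for g in groups:
        ci = np.zeros(k)
        cs = np.zeros(k)
        ci[0] = 1.0
        cs[1] = 1.0
        if g != groups[0]:
            ci[names.index(f"g[{g}]")] = 1.0
            cs[names.index(f"time:g[{g}]")] = 1.0
        intercepts[g] = float(ci @ res.params)
        slopes[g] = float(cs @ res.params)
        i_se[g] = float(np.sqrt(ci @ cov @ ci))
        s_se[g] = float(np.sqrt(cs @ cov @ cs))
    return RegressionComparison(groups, intercepts, slopes, i_se, s_se,
                                f_stat=f_stat, p_value=p_value,
                                df_num=len(inter_idx),
                                df_resid=int(res.df_resid),
                                n_points=len(df))


def traces_to_regression_frame(traces_by_group: dict,
                               window: tuple | None = None) -> pd.DataFrame:
    """Tidy (group, track_id, time, ri) frame of post-stimulation points.

    ``time`` is frame minus stimulation onset; ``window`` optionally
    restricts to a half-open sub-window of relative time.
    """
    rows = []
    for group, traces in traces_by_group.items():
        for tr in traces:
            m = tr.stim_mask()
            t = tr.frames[m] - tr.stim_frame
            ri = tr.ri[m]
            if window is not None:
                w = (t >= window[0]) & (t < window[1])
                t, ri = t[w], ri[w]
            for ti, v in zip(t, ri):
                rows.append((group, tr.track_id, int(ti), float(v)))
    return pd.DataFrame(rows, columns=["group", "track_id", "time", "ri"])


def compare_unloading_regressions(traces_by_group: dict,
                                  window: tuple | None = None
                                  ) -> RegressionComparison:
    """Compare destaining regression lines between genotype groups.

    ``traces_by_group`` maps group label to a list of
    :class:`destain.kinetics.BoutonTrace`; each group needs >= 2 traces.
    """
    for g, traces in traces_by_group.items():
        if len(traces) < 2:
            raise ValidationError(
                f"compare_unloading_regressions: group {g!r} has "
                f"{len(traces)} traces (need >= 2)")
    df = traces_to_regression_frame(traces_by_group, window=window)
    if df["time"].nunique() < 3:
        raise ValidationError(
            "compare_unloading_regressions: window covers < 3 frames")
    return compare_regression_lines(df)


def per_trace_slope_test(traces_by_group: dict, n_permutations: int = 10_000,
                         seed: int | None = None) -> PermutationTestResult:
    """Robustness mode: permutation test on per-trace OLS slopes.

    Summarizes each trace by its post-stimulation OLS slope, then runs
    the two-sample permutation test between the two groups, avoiding the
    pooled model's assumption of point-level independence.
    """
    groups = sorted(traces_by_group)
    if len(groups) != 2:
        raise ValidationError("per_trace_slope_test: need exactly 2 groups")
    slopes = {}
    for g in groups:
        vals = []
        for tr in traces_by_group[g]:
            m = tr.stim_mask()
            if m.sum() >= 3:
                vals.append(np.polyfit(tr.frames[m].astype(float), tr.ri[m], 1)[0])
        slopes[g] = vals
    return permutation_t_test(slopes[groups[0]], slopes[groups[1]],
                              n_permutations=n_permutations, seed=seed)


# ---------------------------------------------------------------------------
# Correlation and EM report
# ---------------------------------------------------------------------------

def pearson_correlation(x, y) -> CorrelationResult:
    """Sample Pearson r with the two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError(
            f"pearson_correlation: need paired samples with n >= 3, "
            f"got {len(x)}, {len(y)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("pearson_correlation: non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError(
            "pearson_correlation: zero variance in one of the variables")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), len(x), float(p))


EM_METRICS = ["az_length_nm", "presyn_area_um2", "vesicle_density_per_um2"]


def em_analysis(records: pd.DataFrame, n_permutations: int = 10_000,
                seed: int | None = None) -> pd.DataFrame:
    """Full ultrastructure report for a two-group EM table.

    Per metric (AZ length, presynaptic area, vesicle density): a
    permutation test between the two groups, with a Benjamini-Hochberg
    q value column alongside the raw p values.  Per group: the Pearson
    correlation of vesicle density with AZ length.
    """
    missing = [c for c in EM_METRICS + ["group"] if c not in records.columns]
    if missing:
        raise ValidationError(f"em_analysis: missing column(s) {missing}")
    groups = sorted(records["group"].unique())
    if len(groups) != 2:
        raise ValidationError(f"em_analysis: need exactly 2 groups, got {groups}")
    for g in groups:
        if (records["group"] == g).sum() < 3:
            raise ValidationError(f"em_analysis: group {g!r} has < 3 records")

    rows = []
    pvals = []
    for i, metric in enumerate(EM_METRICS):
        a = records.loc[records["group"] == groups[0], metric]
        b = records.loc[records["group"] == groups[1], metric]
        res = permutation_t_test(a, b, n_permutations=n_permutations,
                                 seed=None if seed is None else seed + i)
        rows.append(dict(analysis="permutation_test", metric=metric,
                         group=f"{groups[0]}-{groups[1]}",
                         statistic=res.observed_statistic,
                         p_value=res.p_value, n=len(a) + len(b)))
        pvals.append(res.p_value)
    qvals = sm.stats.multipletests(pvals, method="fdr_bh")[1]
    for row, q in zip(rows, qvals):
        row["q_value"] = float(q)
    for g in groups:
        sub = records[records["group"] == g]
        corr = pearson_correlation(sub["az_length_nm"],
                                   sub["vesicle_density_per_um2"])
        rows.append(dict(analysis="density_az_correlation", metric="pearson_r",
                         group=g, statistic=corr.r, p_value=corr.p_value,
                         q_value=np.nan, n=corr.n))
    report = pd.DataFrame(rows, columns=["analysis", "metric", "group",
                                         "statistic", "p_value", "q_value", "n"])
    log_stage("em_analysis", records=len(records), tests=len(report))
    return report
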