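"""Permutation tests, regression-line comparison and Pearson correlation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from destain.errors import DegenerateInputError, ValidationError
from destain.kinetics import BoutonTrace
from destain.simulate import EMSimConfig, simulate_em_dataset, simulate_trace
from destain.stats import (compare_regression_lines,
                           compare_unloading_regressions, em_analysis,
                           pearson_correlation, permutation_t_test,
                           per_trace_slope_test)


def exhaustive_perm_p(x, y):
    """Independent brute-force enumeration of the two-sided permutation p."""
    pooled = np.concatenate([x, y])
    n = len(x)
    t_obs = abs(np.mean(x) - np.mean(y))
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), bool)
        mask[list(idx)] = True
        t = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += t >= t_obs - 1e-12
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# permutation_t_test
# ---------------------------------------------------------------------------

def test_identical_samples_give_p_one():
    res = permutation_t_test([3.0, 1.0, 2.0], [2.0, 3.0, 1.0])
    assert res.observed_statistic == 0.0
    assert res.p_value == 1.0


@pytest.mark.parametrize("x, y, expected", [
    ([1, 2], [3, 4], 2 / 6),
    (list(range(1, 6)), list(range(11, 16)), 2 / 252),
])
def test_exhaustive_p_known_fixtures(x, y, expected):
    res = permutation_t_test(x, y)
    assert res.exhaustive
    assert res.p_value == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_exhaustive_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(0, 1, 5), rng.normal(0.5, 1, 4)
    res = permutation_t_test(x, y)
    assert res.p_value == pytest.approx(exhaustive_perm_p(x, y), abs=1e-12)


def test_exhaustive_matches_scipy_reference():
    # equal group sizes: the |T| tail and scipy's doubled one-sided tail
    # coincide for the symmetric null
    rng = np.random.default_rng(10)
    x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
    ours = permutation_t_test(x, y)
    ref = sps.permutation_test(
        (x, y), lambda a, b, axis=-1: np.mean(a, axis=axis) - np.mean(b, axis=axis),
        permutation_type="independent", n_resamples=np.inf, alternative="two-sided")
    assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_monte_carlo_close_to_exhaustive():
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 6), rng.normal(0.5, 1, 6)
    exact = permutation_t_test(x, y).p_value
    mc = permutation_t_test(x, y, exhaustive=False, n_permutations=100_000,
                            seed=0).p_value
    assert abs(mc - exact) <= 0.01


@settings(derandomize=True, deadline=None, max_examples=25)
@given(st.integers(0, 2 ** 31 - 1))
def test_permutation_symmetry(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(0, 1, 5), rng.normal(1, 2, 6)
    a = permutation_t_test(x, y)
    b = permutation_t_test(y, x)
    assert a.observed_statistic == pytest.approx(-b.observed_statistic)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


def test_small_group_rejected():
    with pytest.raises(ValidationError):
        permutation_t_test([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# regression-line comparison
# ---------------------------------------------------------------------------

def _line_df(slopes, intercept=1.0, n_t=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, slope in slopes.items():
        t = np.tile(np.arange(n_t, dtype=float), 3)
        ri = intercept + slope * t + (rng.normal(0, noise, len(t)) if noise else 0)
        rows.append(pd.DataFrame({"group": g, "time": t, "ri": ri}))
    return pd.concat(rows, ignore_index=True)


def test_identical_noiseless_lines_have_zero_interaction():
    # perfect fit: the interaction (slope-difference) estimate is zero;
    # the F ratio itself is 0/0 and not meaningful in this degenerate case
    df = _line_df({"KO": -0.002, "WT": -0.002})
    cmp = compare_regression_lines(df)
    assert cmp.slopes["KO"] == pytest.approx(cmp.slopes["WT"], abs=1e-14)
    assert cmp.intercepts["KO"] == pytest.approx(cmp.intercepts["WT"], abs=1e-12)


def test_noiseless_lines_recovered_to_machine_precision():
    df = _line_df({"KO": -0.002, "WT": -0.001}, intercept=0.9)
    cmp = compare_regression_lines(df)
    assert cmp.slopes["KO"] == pytest.approx(-0.002, abs=1e-12)
    assert cmp.slopes["WT"] == pytest.approx(-0.001, abs=1e-12)
    assert cmp.intercepts["KO"] == pytest.approx(0.9, abs=1e-12)
    assert cmp.p_value < 1e-10  # slope difference detected


def test_collinear_design_rejected():
    df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                       "time": [1.0] * 6, "ri": [1, 2, 3, 4, 5, 6]})
    with pytest.raises(DegenerateInputError):
        compare_regression_lines(df)


def _trace_group(depths, n_frames=120, stim_frame=20, stim_duration=100,
                 noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i, d in enumerate(depths):
        s = simulate_trace(d, n_frames=n_frames, stim_frame=stim_frame,
                           stim_duration=stim_duration, noise_sd=noise,
                           rng=rng)
        out.append(BoutonTrace(i, np.arange(n_frames), s, stim_frame,
                               stim_duration))
    return out


def test_trace_level_interface_and_robustness_mode():
    by_group = {"KO": _trace_group([0.35] * 6, seed=1),
                "WT": _trace_group([0.18] * 6, seed=2)}
    cmp = compare_unloading_regressions(by_group)
    assert cmp.slopes["KO"] < cmp.slopes["WT"] < 0
    assert cmp.p_value < 1e-6
    robust = per_trace_slope_test(by_group, seed=0)
    assert robust.p_value < 0.05


def test_group_with_one_trace_rejected():
    by_group = {"KO": _trace_group([0.3]), "WT": _trace_group([0.2] * 3)}
    with pytest.raises(ValidationError, match="KO"):
        compare_unloading_regressions(by_group)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def test_pearson_exact_values():
    x = np.array([1.0, 2.0, 3.0])
    assert pearson_correlation(x, 2 * x + 1).r == pytest.approx(1.0)
    assert pearson_correlation(x, -x).r == pytest.approx(-1.0)
    assert pearson_correlation(x, [1.0, 3.0, 2.0]).r == pytest.approx(0.5)


@settings(derandomize=True, deadline=None, max_examples=25)
@given(st.integers(0, 2 ** 31 - 1))
def test_pearson_affine_invariance(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
    r0 = pearson_correlation(x, y).r
    assert pearson_correlation(3 * x + 2, y).r == pytest.approx(r0, abs=1e-9)
    assert pearson_correlation(-2 * x, y).r == pytest.approx(-r0, abs=1e-9)


def test_pearson_degenerate_inputs():
    with pytest.raises(DegenerateInputError):
        pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValidationError):
        pearson_correlation([1.0, 2.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# EM report
# ---------------------------------------------------------------------------

def test_em_analysis_missing_column():
    df = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3,
                       "az_length_nm": np.arange(6) + 1.0})
    with pytest.raises(ValidationError, match="missing"):
        em_analysis(df)


def test_em_analysis_null_and_shift():
    cfg = EMSimConfig(n_per_group=20, groups=("a", "b"),
                      density_az_correlation={"a": 0.0, "b": 0.0}, seed=6)
    df = simulate_em_dataset(cfg)
    report = em_analysis(df, seed=0)
    perm = report[report.analysis == "permutation_test"]
    assert len(perm) == 3 and (perm.p_value > 0).all()
    # clear AZ-length shift of 2 group SDs is detected
    df2 = df.copy()
    df2.loc[df2.group == "b", "az_length_nm"] += 200.0
    rep2 = em_analysis(df2, seed=0)
    p = rep2[(rep2.analysis == "permutation_test")
             & (rep2.metric == "az_length_nm")].p_value.iloc[0]
    assert p < 0.01
    # q values are BH-monotone transforms of the raw p values
    assert (perm.q_value >= perm.p_value - 1e-12).all()
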