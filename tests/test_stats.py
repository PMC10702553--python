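"""Reliability statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from gratio.stats import (
    bland_altman,
    icc_band,
    icc_single_rating,
    paired_compare,
    parallel_sections_anova,
)


def icc31_mean_squares_oracle(table):
    """ICC(3,1) from the two-way ANOVA decomposition, written with loops."""
    n, k = table.shape
    grand = sum(table[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(table[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((table[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_rows = ss_rows / (n - 1)
    ms_err = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


def wilcoxon_enumeration_oracle(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0  # no ties by construction
    t_plus = ranks[d > 0].sum()
    n = len(d)
    stats = [
        sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)
    ]
    stats = np.array(stats)
    total = ranks.sum()
    t_min = min(t_plus, total - t_plus)
    # two-sided: both tails at the observed min statistic
    p = (np.sum(stats <= t_min) + np.sum(stats >= total - t_min)) / len(stats)
    return min(1.0, p)


# -- ICC ---------------------------------------------------------------------


def test_icc_identical_columns():
    x = np.tile(np.arange(10.0)[:, None], (1, 2))
    res = icc_single_rating(x)
    assert res.icc == 1.0
    assert res.band == "excellent"


def test_icc_matches_oracle_on_hand_table():
    table = np.array(
        [[9.0, 2.0], [8.0, 1.0], [7.0, 3.0], [10.0, 4.0], [6.0, 2.0], [8.5, 3.5]]
    )
    res = icc_single_rating(table)
    assert res.icc == pytest.approx(icc31_mean_squares_oracle(table), abs=1e-10)


def test_icc_matches_oracle_on_random_tables():
    rng = np.random.default_rng(12)
    for _ in range(50):
        table = rng.normal(size=(10, 2))
        res = icc_single_rating(table)
        assert res.icc == pytest.approx(icc31_mean_squares_oracle(table), abs=1e-10)
        assert res.ci95[0] <= res.icc <= res.ci95[1]


def test_icc_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(5)
    table = rng.normal(size=(20, 3))
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(20), 3),
            "rater": np.tile(np.arange(3), 20),
            "value": table.ravel(),
        }
    )
    ref = pingouin.intraclass_corr(long, targets="subject", raters="rater", ratings="value")
    ref_row = ref[ref["Type"].isin(["ICC3", "ICC(C,1)"])].iloc[0]
    res = icc_single_rating(table)
    assert res.icc == pytest.approx(ref_row["ICC"], abs=1e-10)
    assert res.f_stat == pytest.approx(ref_row["F"], abs=1e-8)
    assert res.p_value == pytest.approx(ref_row["pval"], abs=1e-10)
    assert res.ci95 == pytest.approx(tuple(ref_row["CI95"]), abs=0.01)  # pingouin rounds


def test_icc_noise_equal_to_subject_sd():
    """Both raters carry independent noise with SD equal to the subject SD:
    the consistency ICC approaches sigma_s^2/(sigma_s^2 + sigma_e^2) = 0.5."""
    rng = np.random.default_rng(7)
    subjects = rng.normal(0.0, 1.0, size=200)
    table = np.stack(
        [subjects + rng.normal(0.0, 1.0, 200), subjects + rng.normal(0.0, 1.0, 200)], axis=1
    )
    res = icc_single_rating(table)
    assert res.icc == pytest.approx(0.5, abs=0.1)


def test_icc_band_boundaries_exact():
    assert icc_band(0.4999999) == "poor"
    assert icc_band(0.50) == "fair"
    assert icc_band(0.7499999) == "fair"
    assert icc_band(0.75) == "good"
    assert icc_band(0.8999999) == "good"
    assert icc_band(0.90) == "excellent"


def test_icc_input_validation():
    with pytest.raises(ValueError):
        icc_single_rating(np.zeros((3, 2)))  # too few subjects
    bad = np.ones((6, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        icc_single_rating(bad)


def test_icc_zero_variance_degenerate():
    res = icc_single_rating(np.ones((6, 2)))
    assert res.degenerate


# -- Bland-Altman ------------------------------------------------------------


def test_bland_altman_identical():
    a = np.arange(10.0)
    res = bland_altman(a, a)
    assert res.bias == 0.0
    assert res.loa == (0.0, 0.0)


def test_bland_altman_constant_difference():
    a = np.arange(10.0)
    res = bland_altman(a + 0.3, a)
    assert res.bias == pytest.approx(0.3)
    assert res.sd_diff == pytest.approx(0.0)
    assert res.loa[0] == pytest.approx(0.3) and res.loa[1] == pytest.approx(0.3)


def test_bland_altman_closed_form():
    rng = np.random.default_rng(123)
    b = rng.normal(5.0, 1.0, 1000)
    a = b + rng.normal(0.2, 0.1, 1000)
    res = bland_altman(a, b)
    se_bias = 0.1 / np.sqrt(1000)
    se_loa = 0.1 * np.sqrt(3.0 / 1000)
    assert res.bias == pytest.approx(0.2, abs=3 * se_bias)
    assert res.loa[0] == pytest.approx(0.2 - 1.96 * 0.1, abs=3 * se_loa)
    assert res.loa[1] == pytest.approx(0.2 + 1.96 * 0.1, abs=3 * se_loa)
    assert res.loa == pytest.approx(
        (res.bias - 1.96 * res.sd_diff, res.bias + 1.96 * res.sd_diff), abs=1e-12
    )


def test_bland_altman_detects_proportional_bias():
    rng = np.random.default_rng(3)
    b = rng.normal(5.0, 1.0, 500)
    a = b + 0.2 * b + rng.normal(0.0, 0.05, 500)  # difference grows with level
    res = bland_altman(a, b)
    assert res.proportional_bias_p < 0.001
    assert res.proportional_bias_slope > 0.1


def test_bland_altman_validation():
    with pytest.raises(ValueError):
        bland_altman(np.arange(4.0), np.arange(5.0))


# -- paired comparison --------------------------------------------------------


def test_paired_identical_is_degenerate():
    x = np.arange(10.0)
    res = paired_compare(x, x)
    assert res.degenerate
    assert res.p_value == 1.0


@pytest.mark.filterwarnings("ignore:Precision loss")
def test_paired_large_shift_detected():
    rng = np.random.default_rng(0)
    y = rng.normal(0.0, 1.0, 50)
    x = y + 5.0  # five SDs
    res = paired_compare(x, y)
    assert res.p_value < 0.001
    assert res.wilcoxon_p < 0.001 and res.t_p < 0.001


def test_wilcoxon_matches_enumeration_at_n8():
    rng = np.random.default_rng(21)
    y = rng.normal(0.0, 1.0, 8)
    x = y + rng.normal(0.6, 0.7, 8)
    res = paired_compare(x, y)
    assert res.wilcoxon_p == pytest.approx(wilcoxon_enumeration_oracle(x - y), abs=1e-12)


def test_gate_switches_on_normality():
    rng = np.random.default_rng(2)
    # heavy-tailed differences: normality rejected, Wilcoxon used
    y = np.zeros(60)
    x = rng.standard_cauchy(60)
    res = paired_compare(x, y)
    assert res.normality_p < 0.05 and res.test_used == "wilcoxon"
    # clean normal differences: paired t used
    x2 = y + rng.normal(0.1, 1.0, 60)
    res2 = paired_compare(x2, y)
    if res2.normality_p >= 0.05:
        assert res2.test_used == "paired_t"


def test_paired_gate_type1_rate():
    """Overall false-positive rate of the gated test stays near 5%."""
    rng = np.random.default_rng(99)
    rejections = 0
    reps = 400
    for _ in range(reps):
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.0, 1.0, 30)
        if paired_compare(x, y).p_value < 0.05:
            rejections += 1
    assert 0.03 <= rejections / reps <= 0.07


# -- one-way ANOVA ------------------------------------------------------------


def test_anova_identical_groups():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    f, p = parallel_sections_anova([g, g.copy(), g.copy()])
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_anova_power_at_large_separation():
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 1.0, 30)
    b = rng.normal(10.0, 1.0, 30)
    f, p = parallel_sections_anova([a, b])
    assert p < 1e-6


def test_anova_null_p_uniform():
    """Under the null, p-values over seeded repeats look uniform (KS test)."""
    from scipy import stats as sps

    rng = np.random.default_rng(17)
    ps = []
    for _ in range(200):
        groups = [rng.normal(0.0, 1.0, 40) for _ in range(3)]
        ps.append(parallel_sections_anova(groups)[1])
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_anova_validation():
    with pytest.raises(ValueError):
        parallel_sections_anova([np.arange(3.0)])
    with pytest.raises(ValueError):
        parallel_sections_anova([np.arange(3.0), np.array([1.0])])
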