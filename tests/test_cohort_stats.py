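"""Statistics engine vs independent brute-force oracles.

The implementation delegates to scipy; every oracle here is computed from
first principles (hypergeometric enumeration, rank enumeration, the
summary-statistic t formulas) so the two routes stay independent.
"""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from vesselperm.cohort_stats import (
    chi_square_rxc,
    compare_groups,
    fisher_exact_2x2,
    format_p,
    levene,
    spearman,
    ttest_from_summary,
    ttest_two_sample,
    wilcoxon_ranksum,
)
from vesselperm.synthetic import generate_cohort


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-7))


def pooled_t_oracle(m1, s1, n1, m2, s2, n2):
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t = (m2 - m1) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return t, df, 2 * sps.t.sf(abs(t), df)


def ranksum_exact_oracle(x, y):
    """Two-sided exact rank-sum p by enumerating all label assignments."""
    combined = np.concatenate([x, y])
    n, nx = combined.size, len(x)
    ranks = sps.rankdata(combined)
    w_obs = ranks[:nx].sum()
    ws = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(n), nx)]
    mean_w = np.mean(ws)
    extreme = sum(abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9 for w in ws)
    return extreme / len(ws)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def test_summary_t_reproduces_age_comparison():
    # mean age 37.7 +/- 10.2 (n=23) vs 50.0 +/- 10.4 (n=10), pooled
    r = ttest_from_summary(37.7, 10.2, 23, 50.0, 10.4, 10, variant="pooled")
    assert format_p(r.p_value) == ".003"
    t, df, p = pooled_t_oracle(37.7, 10.2, 23, 50.0, 10.4, 10)
    assert r.statistic == pytest.approx(t, rel=1e-12)
    assert r.df == df
    assert r.p_value == pytest.approx(p, rel=1e-12)


def test_summary_t_welch_variant_differs():
    r = ttest_from_summary(37.7, 10.2, 23, 50.0, 10.4, 10, variant="welch")
    assert r.statistic == pytest.approx(3.14, abs=0.01)
    assert r.df == pytest.approx(16.9, abs=0.1)
    assert r.p_value == pytest.approx(0.006, abs=5e-4)


def test_identical_summaries_give_p_one():
    r = ttest_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
    assert r.statistic == 0.0
    assert r.p_value == 1.0


def test_raw_data_pooled_equals_summary_test():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 12), rng.normal(0.5, 1.2, 15)
    raw = ttest_two_sample(x, y, variant="pooled")
    summ = ttest_from_summary(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )
    assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
    assert raw.p_value == pytest.approx(summ.p_value, abs=1e-12)
    same = ttest_two_sample(x, x)
    assert same.p_value == 1.0


def test_two_sample_power_at_group_summaries():
    """Acute vs no-event Ktrans summaries are far apart: simulated samples
    at those summaries reject at alpha=.05 in >= 99% of replicates."""
    rng = np.random.default_rng(1)
    hits = 0
    for _ in range(500):
        x = rng.normal(0.098, 0.038, 10)
        y = rng.normal(0.007, 0.001, 10)
        if ttest_two_sample(x, y, variant="welch").p_value < 0.05:
            hits += 1
    assert hits >= 495


def test_pooled_t_type_one_error_calibration():
    """Under H0 (equal-variance normals) the pooled t rejects at about the
    nominal rate: 0.05 +/- 0.01 over 10,000 seeded replicates."""
    rng = np.random.default_rng(2)
    n1 = n2 = 15
    x = rng.normal(0, 1, (10000, n1))
    y = rng.normal(0, 1, (10000, n2))
    m1, s1 = x.mean(1), x.std(1, ddof=1)
    m2, s2 = y.mean(1), y.std(1, ddof=1)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t = (m2 - m1) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(np.abs(t), n1 + n2 - 2)
    rate = (p < 0.05).mean()
    assert 0.04 <= rate <= 0.06
    # spot-check the implementation agrees with the vectorized oracle
    r = ttest_two_sample(x[0], y[0], variant="pooled")
    assert r.p_value == pytest.approx(p[0], rel=1e-10)


# ---------------------------------------------------------------------------
# levene
# ---------------------------------------------------------------------------

def test_levene_identical_samples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    r = levene(x, x)
    assert r.statistic == pytest.approx(0.0, abs=1e-12)
    assert r.p_value == pytest.approx(1.0)


def test_levene_type_one_error_and_power():
    rng = np.random.default_rng(3)
    rej_null = 0
    rej_alt = 0
    for _ in range(1000):
        if levene(rng.normal(0, 1, 50), rng.normal(0, 1, 50)).p_value < 0.05:
            rej_null += 1
        if levene(rng.normal(0, 1, 50), rng.normal(0, 3, 50)).p_value < 0.05:
            rej_alt += 1
    assert 0.03 <= rej_null / 1000 <= 0.07
    assert rej_alt / 1000 > 0.9


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

def test_ranksum_small_sample_exact():
    # (1,2) vs (3,4): 2 of the C(4,2)=6 assignments are as extreme
    r = wilcoxon_ranksum([1.0, 2.0], [3.0, 4.0])
    assert r.p_value == pytest.approx(1.0 / 3.0, rel=1e-12)
    assert "exact" in r.method


def test_ranksum_identical_samples():
    x = [1.0, 2.0, 3.0]
    assert wilcoxon_ranksum(x, x).p_value == pytest.approx(1.0)


def test_ranksum_matches_enumeration_oracle():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 5)
    y = rng.normal(0.8, 1, 5)
    r = wilcoxon_ranksum(x, y)
    assert r.p_value == pytest.approx(ranksum_exact_oracle(x, y), abs=1e-9)


def test_ranksum_approximation_close_to_exact():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 8)
    y = rng.normal(1.0, 1, 8)
    exact = ranksum_exact_oracle(x, y)
    # force the large-sample branch by adding a tie far from the data
    approx = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert approx.pvalue == pytest.approx(exact, abs=0.01)
    assert wilcoxon_ranksum(x, y).p_value == pytest.approx(exact, abs=1e-9)


def test_ranksum_reports_median_iqr():
    r = wilcoxon_ranksum([1.0, 2.0, 3.0, 10.0], [4.0, 5.0, 6.0, 7.0])
    med, iqr = r.notes["median_iqr_x"]
    assert med == pytest.approx(2.5)
    assert iqr == pytest.approx(np.percentile([1, 2, 3, 10], 75) - np.percentile([1, 2, 3, 10], 25))


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def test_chi_square_reproduces_smoking_comparisons():
    r = chi_square_rxc([[15, 8], [2, 8]])
    assert r.statistic == pytest.approx(5.70, abs=0.01)
    assert format_p(r.p_value) == ".017"
    r2 = chi_square_rxc([[15, 8], [1, 2]])
    assert r2.statistic == pytest.approx(1.14, abs=0.01)
    assert format_p(r2.p_value) == ".286"


def test_chi_square_null_table_and_margins():
    r = chi_square_rxc([[10, 10], [10, 10]])
    assert r.statistic == 0.0
    assert r.p_value == 1.0
    with pytest.raises(ValueError):
        chi_square_rxc([[0, 0], [1, 2]])


def test_chi_square_monotone_in_table_extremity():
    # fixing margins, pushing counts off-diagonal shrinks the p-value
    ps = []
    for shift in range(0, 5):
        ps.append(chi_square_rxc([[10 + shift, 10 - shift],
                                  [10 - shift, 10 + shift]]).p_value)
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_fisher_exact_enumeration_examples():
    # [[15,8],[1,2]]: hypergeometric probs 0.0462/0.2769/0.4616/0.2154
    r = fisher_exact_2x2([[15, 8], [1, 2]])
    assert r.p_value == pytest.approx(0.5385, abs=1e-4)
    assert r.p_value == pytest.approx(fisher_two_sided_oracle([[15, 8], [1, 2]]), rel=1e-9)
    assert fisher_exact_2x2([[2, 0], [0, 2]]).p_value == pytest.approx(1.0 / 3.0, rel=1e-9)
    assert fisher_exact_2x2([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)


def test_fisher_two_sided_vs_one_sided_and_degenerate():
    r = fisher_exact_2x2([[8, 2], [3, 7]])
    assert r.p_value >= r.notes["p_one_sided"]
    degenerate = fisher_exact_2x2([[0, 0], [3, 7]])
    assert degenerate.p_value == 1.0


def test_fisher_matches_oracle_on_random_small_tables():
    rng = np.random.default_rng(6)
    for _ in range(200):
        n = rng.integers(4, 31)
        a = rng.integers(0, n + 1)
        b = rng.integers(0, n - a + 1)
        c = rng.integers(0, n - a - b + 1)
        d = n - a - b - c
        table = [[int(a), int(b)], [int(c), int(d)]]
        if min(sum(table[0]), sum(table[1])) == 0:
            continue
        if min(table[0][0] + table[1][0], table[0][1] + table[1][1]) == 0:
            continue
        assert fisher_exact_2x2(table).p_value == pytest.approx(
            fisher_two_sided_oracle(table), rel=1e-7
        ), table


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------

def test_spearman_monotone_pairs():
    x = np.arange(1.0, 11.0)
    assert spearman(x, np.exp(x)).statistic == pytest.approx(1.0)
    assert spearman(x, -x).statistic == pytest.approx(-1.0)
    assert spearman([1, 2, 3, 4], [2, 1, 4, 3]).statistic == pytest.approx(0.6)


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(seed=1)


def test_dispatch_contingency_reproduces_smoking_p(cohort):
    r = compare_groups(cohort, "smoking", "aetiology",
                       groups=("vasculitis", "atherosclerosis"))
    assert r.notes["branch"] == "chi-square"
    assert format_p(r.p_value) == ".017"
    assert "fisher_p" in r.notes  # exact test reported alongside


def test_dispatch_normal_variable_takes_t_branch():
    rng = np.random.default_rng(7)
    import pandas as pd

    df = pd.DataFrame({
        "g": ["a"] * 20 + ["b"] * 20,
        "v": np.concatenate([rng.normal(0, 1, 20), rng.normal(0.2, 1, 20)]),
    })
    r = compare_groups(df, "v", "g")
    assert r.notes["branch"].startswith("t-test")


def test_dispatch_skewed_variable_takes_wilcoxon_branch():
    """Heavily skewed (lognormal) group data fail the normality gate in
    >= 90% of seeded replicates."""
    import pandas as pd

    rng = np.random.default_rng(8)
    wilcoxon = 0
    for _ in range(200):
        df = pd.DataFrame({
            "g": ["a"] * 15 + ["b"] * 15,
            "v": np.concatenate([
                rng.lognormal(0, 1.5, 15), rng.lognormal(0.3, 1.5, 15)
            ]),
        })
        if compare_groups(df, "v", "g").notes["branch"] == "wilcoxon":
            wilcoxon += 1
    assert wilcoxon >= 180


def test_dispatcher_deterministic(cohort):
    r1 = compare_groups(cohort, "ktrans_lesion", "infarct_stage",
                        groups=("acute_subacute", "none"))
    r2 = compare_groups(cohort, "ktrans_lesion", "infarct_stage",
                        groups=("acute_subacute", "none"))
    assert r1.p_value == r2.p_value
    assert r1.notes["branch"] == r2.notes["branch"]


def test_all_p_values_in_unit_interval(cohort):
    for var in ("smoking", "drinking", "hypertension", "age", "ktrans_lesion"):
        r = compare_groups(cohort, var, "aetiology",
                           groups=("vasculitis", "atherosclerosis"))
        assert 0.0 <= r.p_value <= 1.0
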