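import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from psypgx.stats import (
    StatsError,
    mcnemar,
    paired_dose_changes,
    paired_power,
    percent_change,
    round_half_up,
    wilcoxon_signed_rank,
    within_patient_variation,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def wilcoxon_enumeration_oracle(diffs, alternative):
    """Exact p by enumerating every sign assignment of the ranked |differences|."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product((0, 1), repeat=n)
    ]
    eps = 1e-9
    cdf = sum(w <= w_obs + eps for w in ws) / 2**n
    sf = sum(w >= w_obs - eps for w in ws) / 2**n
    if alternative == "greater":
        return sf
    if alternative == "less":
        return cdf
    return min(1.0, 2.0 * min(cdf, sf))


def mcnemar_binomial_oracle(b, c):
    """Exact two-sided p as a sum of binomial(b+c, 1/2) tail terms."""
    n = b + c
    if n == 0:
        return 1.0
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2**n
    return min(1.0, 2 * tail)


# ---------------------------------------------------------------------------
# percent change & variation


@pytest.mark.parametrize(
    "before, after, expected",
    [(343, 239, -30.32), (78, 25, -67.95), (5, 5, 0.0), (100, 150, 50.0)],
)
def test_percent_change_examples(before, after, expected):
    assert round_half_up(percent_change(before, after)) == pytest.approx(expected)


def test_percent_change_zero_baseline_rejected():
    with pytest.raises(StatsError):
        percent_change(0, 10)


def test_percent_change_is_not_symmetric():
    # a -30.32% reduction does not invert to a +30.32% increase
    down = percent_change(343, 239)
    up = percent_change(239, 343)
    assert down != pytest.approx(-up)
    assert (1 + down / 100) * (1 + up / 100) == pytest.approx(1.0)


def test_within_patient_variation_degenerate_and_hand_computed():
    v = within_patient_variation([-50.0, -50.0, -50.0])
    assert (v.mean, v.sd) == (-50.0, 0.0)
    assert v.ci_low == v.ci_high == -50.0

    v = within_patient_variation([-20.0, -40.0])
    assert v.mean == pytest.approx(-30.0)
    assert v.sd == pytest.approx(math.sqrt(200), abs=1e-9)  # 14.142...
    assert v.ci_low <= v.mean <= v.ci_high


def test_within_patient_variation_empty_rejected():
    with pytest.raises(StatsError):
        within_patient_variation([])


def test_paired_dose_change_conventions():
    pre = {"A": 100.0, "B": 200.0, "C": 50.0}
    post = {"A": 50.0, "B": 0.0}
    keeping = paired_dose_changes(pre, post, include_switches=False)
    switching = paired_dose_changes(pre, post, include_switches=True)
    assert keeping == [-50.0]  # only A has the drug in both epochs
    assert sorted(switching) == [-100.0, -100.0, -50.0]  # B, C discontinued


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def test_wilcoxon_all_increases_one_tailed():
    res = wilcoxon_signed_rank([1, 2, 3], [2, 4, 6], alternative="less")
    assert res.p_value == pytest.approx(0.125)  # 1/2^3
    assert res.n_effective == 3


def test_wilcoxon_identical_pairs():
    res = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
    assert res.p_value == 1.0 and res.n_effective == 0


@pytest.mark.parametrize("n", range(2, 13))
def test_wilcoxon_exact_matches_enumeration(n):
    rng = np.random.default_rng(1234 + n)
    for _ in range(5):
        d = rng.integers(-8, 9, size=n).astype(float)
        for alt in ("two-sided", "greater", "less"):
            got = wilcoxon_signed_rank(d, alternative=alt).p_value
            want = wilcoxon_enumeration_oracle(d, alt)
            assert got == pytest.approx(want, abs=1e-12), (list(d), alt)


def test_wilcoxon_exact_matches_scipy_without_ties():
    rng = np.random.default_rng(7)
    d = rng.permutation(np.arange(1, 13)) * np.where(rng.random(12) < 0.5, -1, 1)
    ours = wilcoxon_signed_rank(d).p_value
    ref = sps.wilcoxon(d, method="exact").pvalue
    assert ours == pytest.approx(ref, rel=1e-10)


def test_wilcoxon_large_sample_normal_approximation():
    rng = np.random.default_rng(11)
    d = rng.normal(0.6, 1.0, size=60)
    ours = wilcoxon_signed_rank(d).p_value
    ref = sps.wilcoxon(d, method="approx", correction=True).pvalue
    assert ours == pytest.approx(ref, rel=1e-6)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.integers(-9, 9), min_size=1, max_size=10))
def test_wilcoxon_exact_property_any_differences(diffs):
    d = [float(x) for x in diffs]
    for alt in ("two-sided", "greater", "less"):
        got = wilcoxon_signed_rank(d, alternative=alt).p_value
        assert got == pytest.approx(wilcoxon_enumeration_oracle(d, alt), abs=1e-12)


# ---------------------------------------------------------------------------
# McNemar


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(0, 20), st.integers(0, 20))
def test_mcnemar_exact_property(b, c):
    if b + c < 25:
        assert mcnemar(b, c).p_value == pytest.approx(
            mcnemar_binomial_oracle(b, c), abs=1e-12
        )


def test_mcnemar_symmetric_counts():
    assert mcnemar(5, 5).p_value == 1.0


def test_mcnemar_exact_closed_forms():
    res = mcnemar(10, 0)
    assert res.p_value == pytest.approx(2 * 0.5**10)
    res = mcnemar(40, 10)
    assert res.statistic == pytest.approx((abs(40 - 10) - 1) ** 2 / 50)
    assert res.statistic == pytest.approx(16.82)


@pytest.mark.parametrize("b, c", [(0, 0), (1, 0), (3, 2), (7, 7), (12, 8), (20, 0)])
def test_mcnemar_exact_matches_binomial_oracle(b, c):
    assert mcnemar(b, c).p_value == pytest.approx(mcnemar_binomial_oracle(b, c))


def test_mcnemar_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.stats.contingency_tables")
    for b, c in [(3, 1), (10, 5), (40, 10), (60, 45)]:
        table = [[0, b], [c, 0]]
        exact = b + c < 25
        ref = statsmodels.mcnemar(table, exact=exact, correction=True)
        assert mcnemar(b, c).p_value == pytest.approx(ref.pvalue, rel=1e-8)


# ---------------------------------------------------------------------------
# power


def test_power_null_effect_equals_alpha():
    assert paired_power(0, 100, 50, alpha=0.05) == pytest.approx(0.05, abs=1e-6)


def test_power_tends_to_one_as_sd_vanishes():
    assert paired_power(200, 1e-6, 10) > 0.999999


def test_power_monotone_grid():
    base = paired_power(200, 1050, 100)
    assert paired_power(300, 1050, 100) > base  # larger effect
    assert paired_power(200, 1050, 200) > base  # more patients
    assert paired_power(200, 1500, 100) < base  # noisier differences


def test_power_invalid_inputs():
    with pytest.raises(StatsError):
        paired_power(200, 0, 100)
    with pytest.raises(StatsError):
        paired_power(200, 1050, 1)
    with pytest.raises(StatsError):
        paired_power(200, 1050, 100, alpha=1.5)
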