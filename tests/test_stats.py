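"""Goodness-of-fit, contingency and rank-sum engines against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitospectra.io import MutationSet, PointMutation
from mitospectra.stats import (
    ObservedExpected,
    StatsError,
    bonferroni_thresholds,
    chisq_contingency,
    chisq_goodness_of_fit,
    contingency_compare,
    gene_type_gof,
    null_calibration,
    positional_bins,
    wilcoxon_rank_sum,
)


def positions_set(positions):
    return MutationSet.from_mutations(
        [
            PointMutation(position=int(p), ref="A", alt="G", cell_id=f"c{i}")
            for i, p in enumerate(positions)
        ]
    )


# -- chi-squared ---------------------------------------------------------


def pearson_by_hand(observed, expected):
    return sum((o - e) ** 2 / e for o, e in zip(observed, expected))


def test_gof_exact_match_gives_p_one():
    oe = ObservedExpected(("a", "b", "c"), [5, 5, 5], [5, 5, 5])
    res = chisq_goodness_of_fit(oe)
    assert res.statistic == 0 and res.p_value == pytest.approx(1.0)


def test_gof_closed_form_example():
    oe = ObservedExpected(("a", "b"), [10, 0], [5, 5])
    res = chisq_goodness_of_fit(oe)
    assert res.statistic == pytest.approx(10.0)
    assert res.df == 1
    assert res.p_value == pytest.approx(1.565e-3, rel=1e-3)


def test_gof_category_permutation_invariance(rng):
    obs = rng.integers(0, 30, size=6).astype(float)
    exp = rng.uniform(1, 10, size=6)
    exp = exp / exp.sum() * obs.sum()
    base = chisq_goodness_of_fit(ObservedExpected(tuple("abcdef"), obs, exp))
    perm = rng.permutation(6)
    sh = chisq_goodness_of_fit(ObservedExpected(tuple("abcdef"), obs[perm], exp[perm]))
    assert sh.statistic == pytest.approx(base.statistic)
    assert base.statistic == pytest.approx(pearson_by_hand(obs, exp))


def test_observed_expected_invariants():
    with pytest.raises(StatsError):
        ObservedExpected(("a", "b"), [1, 1], [2, 0])  # nonpositive expected
    with pytest.raises(StatsError):
        ObservedExpected(("a", "b"), [1, 1], [5, 5])  # totals differ


# -- positional bins -----------------------------------------------------


def test_positional_bins_layout(ageing_like_cohort):
    from mitospectra.io import filter_coding_region

    oe = positional_bins(filter_coding_region(ageing_like_cohort))
    assert len(oe.categories) == 9  # 16569 = 8 × 2000 + 569
    assert oe.categories[-1] == "16001-16569"
    assert oe.observed.sum() == oe.expected.sum()
    # expectations proportional to overlap with the coding region 577-16023
    widths = [2000 - 576, 2000, 2000, 2000, 2000, 2000, 2000, 2000, 16023 - 16000]
    np.testing.assert_allclose(oe.expected / oe.expected.sum(), np.array(widths) / sum(widths))


def test_positional_bins_concentrated():
    ms = positions_set([1000] * 20)
    oe = positional_bins(ms)
    assert oe.observed[0] == 20 and oe.observed[1:].sum() == 0


def test_positional_bins_equal_mode_and_errors():
    ms = positions_set([1000, 3000])
    oe = positional_bins(ms, equal_expected=True)
    assert np.allclose(oe.expected, oe.expected[0])
    with pytest.raises(StatsError):
        positional_bins(ms, bin_size=0)


def test_gene_type_gof_balanced_is_not_significant(ann):
    """Observed counts set exactly proportional to class lengths → p ≈ 1."""
    lengths = ann.gene_type_lengths(577, 16023)
    positions = []
    codes = ann.class_codes()
    for code, cls in [(0, "protein"), (1, "tRNA"), (2, "rRNA")]:
        pool = np.nonzero(codes == code)[0] + 1
        pool = pool[(pool >= 577) & (pool <= 16023)]
        k = round(200 * lengths[cls] / 15447)
        positions.extend(pool[np.linspace(0, len(pool) - 1, k).astype(int)])
    res = gene_type_gof(positions_set(positions), ann)
    assert res.p_value > 0.5


# -- contingency ---------------------------------------------------------


def test_identical_distributions_give_p_one():
    res = contingency_compare({"a": {"x": 10, "y": 5}, "b": {"x": 10, "y": 5}})
    assert res.overall.statistic == pytest.approx(0.0)
    assert res.overall.p_value == pytest.approx(1.0)


def test_contingency_closed_form_2x2():
    import pandas as pd

    table = pd.DataFrame({"g1": [10, 0], "g2": [0, 10]}, index=["x", "y"])
    res = chisq_contingency(table)
    assert res.statistic == pytest.approx(20.0)  # no continuity correction
    assert res.df == 1
    assert res.p_value == pytest.approx(7.74e-6, rel=1e-2)


def test_contingency_matches_hand_computation(rng):
    import pandas as pd

    arr = rng.integers(5, 40, size=(3, 3)).astype(float)
    res = chisq_contingency(pd.DataFrame(arr))
    row, col, n = arr.sum(1), arr.sum(0), arr.sum()
    expected = np.outer(row, col) / n
    assert res.statistic == pytest.approx(((arr - expected) ** 2 / expected).sum())
    assert res.df == 4


def test_bonferroni_thresholds_printed_values():
    thr = bonferroni_thresholds(3)
    assert thr["*"] == pytest.approx(0.0167, abs=5e-4)
    assert thr["**"] == pytest.approx(0.00333, abs=5e-5)
    assert thr["***"] == pytest.approx(0.000333, abs=5e-6)
    assert bonferroni_thresholds(6)["*"] == pytest.approx(0.00833, abs=5e-5)
    with pytest.raises(StatsError):
        bonferroni_thresholds(0)


def test_pairwise_structure_and_errors():
    groups = {
        "a": {"x": 30, "y": 10},
        "b": {"x": 20, "y": 20},
        "c": {"x": 5, "y": 35},
    }
    res = contingency_compare(groups)
    assert len(res.pairwise) == 3
    for r in res.pairwise.values():
        assert r.thresholds == bonferroni_thresholds(3)
    with pytest.raises(StatsError):
        contingency_compare({"a": {"x": 1}, "b": {"x": 0}})


# -- Wilcoxon rank-sum ---------------------------------------------------


def exact_wilcoxon_oracle(x, y):
    """Brute force: enumerate every assignment of pooled ranks to x."""
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for xi in x for yi in y if xi > yi)
    u_big = max(u_obs, n1 * n2 - u_obs)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx]
        u = sum(1 for xi in xs for yi in ys if xi > yi)
        total += 1
        if max(u, n1 * n2 - u) >= u_big:
            count += 1
    return min(1.0, count / total)


def test_wilcoxon_identical_samples_p_one():
    res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], mode="exact")
    assert res.p_value == pytest.approx(1.0)


def test_wilcoxon_tiny_exact_example():
    res = wilcoxon_rank_sum([1, 2], [3, 4], mode="exact")
    assert res.p_value == pytest.approx(1 / 3)
    assert "exact" in res.method


def test_wilcoxon_empty_sample_errors():
    with pytest.raises(StatsError):
        wilcoxon_rank_sum([], [1.0])


@pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 6) for n2 in range(1, 6)])
def test_exact_matches_enumeration_oracle(n1, n2, rng):
    local = np.random.default_rng(n1 * 31 + n2)
    x = list(local.permutation(np.arange(1.0, n1 + n2 + 1))[:n1])
    y = [v for v in np.arange(1.0, n1 + n2 + 1) if v not in x]
    res = wilcoxon_rank_sum(x, y, mode="exact")
    assert res.p_value == pytest.approx(exact_wilcoxon_oracle(x, y))


def test_normal_approx_close_to_exact_midsize():
    local = np.random.default_rng(99)
    for n in (8, 10, 12):
        vals = local.permutation(np.arange(1.0, 2 * n + 1))
        x, y = list(vals[:n]), list(vals[n:])
        p_exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
        p_norm = wilcoxon_rank_sum(x, y, mode="normal_approx").p_value
        assert abs(p_exact - p_norm) < 0.01


def test_auto_mode_switches_on_ties_and_size():
    assert "exact" in wilcoxon_rank_sum([1, 2], [3, 4]).method
    assert "asymptotic" in wilcoxon_rank_sum([1, 1, 2], [2, 3, 4]).method  # ties
    big = list(range(20))
    assert "asymptotic" in wilcoxon_rank_sum(big, [v + 0.5 for v in big]).method


# -- calibration ---------------------------------------------------------


def test_null_calibration_near_nominal(ann):
    cal = null_calibration(ann, n_mutations=117, n_replicates=3000, seed=11)
    assert cal["positional_rejection_rate"] == pytest.approx(0.05, abs=0.015)
    assert cal["gene_type_rejection_rate"] == pytest.approx(0.05, abs=0.015)
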