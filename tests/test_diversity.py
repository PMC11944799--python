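"""Alpha/beta diversity, ordination, and the statistical test battery."""

import numpy as np
import pandas as pd
import pytest

from rarecycle import (
    alpha_diversity,
    anova_duncan,
    bray_curtis,
    correlation_screen,
    kruskal_wallis,
    mantel,
    nmds,
    permanova,
    pielou,
)
from rarecycle.diversity import DistanceMatrix
from rarecycle.tables import OTUTable


def _table(counts) -> OTUTable:
    counts = np.atleast_2d(counts)
    frame = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(counts.shape[0])],
        columns=[f"o{j}" for j in range(counts.shape[1])],
    )
    return OTUTable(counts=frame, crop=pd.Series("x", index=frame.index))


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def test_alpha_uniform_two_otus():
    profile = alpha_diversity(_table([[5, 5]]))
    assert profile.richness.iloc[0] == 2
    assert profile.shannon.iloc[0] == pytest.approx(np.log(2))
    assert profile.pielou.iloc[0] == pytest.approx(1.0)


def test_alpha_single_otu():
    profile = alpha_diversity(_table([[10, 0, 0]]))
    assert profile.richness.iloc[0] == 1
    assert profile.shannon.iloc[0] == 0.0
    assert profile.pielou.iloc[0] == 0.0


def test_pielou_bounded_and_maximal_at_uniform():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 200, size=(30, 25))
    profile = alpha_diversity(_table(counts))
    assert ((profile.pielou >= 0) & (profile.pielou <= 1)).all()
    uniform = alpha_diversity(_table([[10] * 25]))
    assert profile.shannon.max() <= uniform.shannon.iloc[0] + 1e-12


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def test_bray_curtis_identical_and_disjoint():
    dm = bray_curtis(_table([[1, 2, 0, 0], [1, 2, 0, 0], [0, 0, 3, 1]]))
    assert dm.values[0, 1] == pytest.approx(0.0)
    assert dm.values[0, 2] == pytest.approx(1.0)


def test_bray_curtis_formula_example():
    """counts (1,2) vs (2,1): relative (1/3,2/3) vs (2/3,1/3) -> BC = 1/3."""
    dm = bray_curtis(_table([[1, 2], [2, 1]]))
    assert dm.values[0, 1] == pytest.approx(1 / 3)


def test_bray_curtis_invariants():
    rng = np.random.default_rng(1)
    dm = bray_curtis(_table(rng.integers(0, 50, size=(10, 20)) + 1))
    v = dm.values
    assert np.allclose(v, v.T, atol=1e-12)
    assert np.allclose(np.diag(v), 0)
    assert (v >= 0).all() and (v <= 1).all()


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def test_nmds_line_embeds_with_low_stress():
    x = np.array([0.0, 1.0, 2.0, 4.0])
    d = np.abs(np.subtract.outer(x, x))
    coords, stress = nmds(DistanceMatrix(d, [str(i) for i in x]), seed=0, n_starts=8)
    assert stress < 0.01


def test_nmds_simplex_embeds_exactly():
    d = 1 - np.eye(3)
    _, stress = nmds(DistanceMatrix(d, ["a", "b", "c"]), k=2, seed=0, n_starts=8)
    assert stress < 0.01


def test_nmds_deterministic_under_seed():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(8, 3))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    dm = DistanceMatrix(d, [str(i) for i in range(8)])
    c1, s1 = nmds(dm, seed=5, n_starts=4)
    c2, s2 = nmds(dm, seed=5, n_starts=4)
    assert s1 == s2 and np.array_equal(c1.to_numpy(), c2.to_numpy())


def test_nmds_too_few_samples():
    with pytest.raises(ValueError, match="k"):
        nmds(DistanceMatrix(1 - np.eye(2), ["a", "b"]), k=2)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _brute_force_pseudo_f(d: np.ndarray, groups: np.ndarray):
    """Anderson's pseudo-F from the pairwise-distance definition."""
    n = len(groups)
    ss_total = (d[np.triu_indices(n, 1)] ** 2).sum() / n
    ss_within = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
    a = len(np.unique(groups))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a)), ss_between / ss_total


def test_permanova_matches_brute_force():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(6, 2))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    groups = np.array(["a", "a", "a", "b", "b", "b"])
    res = permanova(DistanceMatrix(d, [str(i) for i in range(6)]), groups, n_perm=99, seed=0)
    f_expected, r2_expected = _brute_force_pseudo_f(d, groups)
    assert res.statistic == pytest.approx(f_expected, rel=1e-10)
    assert res.effect == pytest.approx(r2_expected, rel=1e-10)


def test_permanova_separated_limit():
    x = np.array([[0.0], [0.0], [0.0], [100.0], [100.0], [100.0]])
    d = np.abs(x - x.T)
    res = permanova(
        DistanceMatrix(d, [str(i) for i in range(6)]),
        ["a"] * 3 + ["b"] * 3,
        n_perm=999,
        seed=1,
    )
    assert res.effect == pytest.approx(1.0, abs=1e-9)
    # only label permutations recreating the split can match F_obs, so the
    # p-value sits near the fraction of such permutations (2*3!*3!/6! = 0.1)
    assert 1 / 1000 <= res.p_value < 0.2


def test_permanova_singleton_group_rejected():
    d = 1 - np.eye(4)
    with pytest.raises(ValueError, match="fewer than two"):
        permanova(DistanceMatrix(d, list("abcd")), ["x", "x", "x", "y"])


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def test_mantel_self_correlation():
    rng = np.random.default_rng(4)
    x = rng.normal(size=(8, 2))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    dm = DistanceMatrix(d, [str(i) for i in range(8)])
    res = mantel(dm, dm, n_perm=99, seed=0)
    assert res.statistic == pytest.approx(1.0)


def test_mantel_affine_invariance():
    rng = np.random.default_rng(5)
    x = rng.normal(size=(8, 2))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    ids = [str(i) for i in range(8)]
    res = mantel(
        DistanceMatrix(d, ids), DistanceMatrix(2.5 * d + 1 - np.eye(8), ids),
        method="pearson", n_perm=99, seed=0,
    )
    assert res.statistic == pytest.approx(1.0)


def test_mantel_size_mismatch():
    with pytest.raises(ValueError, match="different samples"):
        mantel(
            DistanceMatrix(1 - np.eye(3), list("abc")),
            DistanceMatrix(1 - np.eye(3), list("xyz")),
        )


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kruskal_textbook_value():
    """(1,2,3) vs (4,5,6): H = 12/(6*7) * (6^2/3 + 15^2/3) - 21 = 3.857."""
    res = kruskal_wallis([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
    assert res.statistic == pytest.approx(3.857, abs=1e-3)


def test_kruskal_identical_values():
    res = kruskal_wallis([2.0] * 6, ["a"] * 3 + ["b"] * 3)
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kruskal_insufficient_groups():
    with pytest.raises(ValueError, match="two observations"):
        kruskal_wallis([1, 2], ["a", "b"])


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

def test_duncan_equal_means_share_letter():
    values = [10, 10.1, 9.9, 10, 10.1, 9.9]
    res = anova_duncan(values, ["a"] * 3 + ["b"] * 3)
    assert res["letters"].nunique() == 1


def test_duncan_separated_groups_distinct_letters():
    values = [1.0, 1.1, 0.9, 100.0, 100.1, 99.9]
    res = anova_duncan(values, ["lo"] * 3 + ["hi"] * 3)
    assert set(res["letters"]) == {"a", "b"}
    assert res.index[0] == "hi"  # sorted by descending mean


def test_duncan_four_groups_match_stepwise_oracle():
    """Two well-separated pairs of close groups -> exactly two letters,
    verified against an independent stepwise-range computation."""
    import scipy.stats as sps

    rng = np.random.default_rng(6)
    data = {
        "g1": 10 + rng.normal(0, 1, 8),
        "g2": 10.3 + rng.normal(0, 1, 8),
        "g3": 20 + rng.normal(0, 1, 8),
        "g4": 20.2 + rng.normal(0, 1, 8),
    }
    values = np.concatenate(list(data.values()))
    groups = np.repeat(list(data), 8)
    res = anova_duncan(values, groups)

    # independent check: critical range for each span, applied to the two
    # cluster gaps and to the within-cluster gaps
    mse = np.mean([np.var(v, ddof=1) for v in data.values()])
    df_err = 32 - 4
    means = sorted((np.mean(v) for v in data.values()), reverse=True)
    for span, hi, lo in [(4, means[0], means[3]), (2, means[0], means[1]), (2, means[2], means[3])]:
        q = sps.studentized_range.ppf((1 - 0.05) ** (span - 1), span, df_err)
        crit = q * np.sqrt(mse / 8)
        if span == 4:
            assert hi - lo > crit  # extremes differ
        else:
            assert hi - lo < crit  # within-cluster pairs do not
    letters = dict(zip(res.index, res["letters"]))
    assert letters["g3"] == letters["g4"]
    assert letters["g1"] == letters["g2"]
    assert letters["g1"] != letters["g3"]


# ---------------------------------------------------------------------------
# Correlation screens
# ---------------------------------------------------------------------------

def test_pearson_perfect_linear():
    x = pd.DataFrame({"x": np.arange(10.0)})
    y = pd.DataFrame({"y": 2 * np.arange(10.0) + 1})
    res = correlation_screen(x, y, "pearson")
    assert res.loc[0, "r"] == pytest.approx(1.0)


def test_spearman_monotone_nonlinear():
    x = pd.DataFrame({"x": np.arange(1.0, 11.0)})
    y = pd.DataFrame({"y": np.exp(np.arange(1.0, 11.0))})
    res = correlation_screen(x, y, "spearman")
    assert res.loc[0, "r"] == pytest.approx(1.0)


def test_spearman_rank_formula_n5():
    """r equals 1 - 6*sum(d^2)/(n(n^2-1)) for a tie-free n=5 fixture."""
    xv = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
    yv = np.array([2.0, 1.0, 5.0, 4.0, 3.0])
    from scipy.stats import rankdata

    d = rankdata(xv) - rankdata(yv)
    expected = 1 - 6 * (d**2).sum() / (5 * 24)
    res = correlation_screen(pd.DataFrame({"x": xv}), pd.DataFrame({"y": yv}), "spearman")
    assert res.loc[0, "r"] == pytest.approx(expected, abs=1e-12)
    assert 0 < res.loc[0, "p"] <= 1  # exact enumeration at small n


def test_constant_column_reported_missing():
    x = pd.DataFrame({"x": np.ones(6)})
    y = pd.DataFrame({"y": np.arange(6.0)})
    with pytest.warns(UserWarning, match="constant"):
        res = correlation_screen(x, y, "pearson")
    assert np.isnan(res.loc[0, "r"])
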