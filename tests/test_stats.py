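"""Rank statistics against brute-force and scipy/statsmodels oracles."""

import itertools

import numpy as np
import pytest
import scipy.stats as st

from arraystrain.stats import anova_tukey, correlate_strain_metrics, kw_dunn, spearman


# -- independent brute-force implementations used as oracles ---------------

def brute_spearman(x, y):
    rx = st.rankdata(x)
    ry = st.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def brute_kruskal_h(groups):
    pooled = np.concatenate(groups)
    ranks = st.rankdata(pooled)
    N = len(pooled)
    idx = 0
    H = 0.0
    for g in groups:
        r = ranks[idx: idx + len(g)]
        idx += len(g)
        H += r.sum() ** 2 / len(g)
    H = 12.0 / (N * (N + 1)) * H - 3 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    H /= 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H


def test_spearman_monotone_examples():
    assert spearman([1, 2, 3], [2, 4, 6]).statistic == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [9, 7, 5, 1]).statistic == pytest.approx(-1.0)


def test_spearman_classic_small_case():
    # Sum of squared rank differences = 6 -> rho = 1 - 6*6/(3*8) = -0.5
    res = spearman([1, 2, 3], [3, 1, 2])
    assert res.statistic == pytest.approx(-0.5)
    # exact permutation p: every permutation of 3 ranks has |rho| >= 0.5
    # (the distribution is {+-1, +-0.5, +-0.5}), so p = 1
    assert res.p_value == pytest.approx(1.0)


def test_spearman_matches_brute_force_on_random_small_sets():
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = rng.integers(4, 13)
        x = rng.integers(0, 6, n).astype(float)  # ties included
        y = rng.integers(0, 6, n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        ours = spearman(x, y)
        assert ours.statistic == pytest.approx(brute_spearman(x, y),
                                               abs=1e-10)
        sp = st.spearmanr(x, y)
        assert ours.statistic == pytest.approx(sp.statistic, abs=1e-10)
        if n > 9:  # both use the t approximation there
            assert ours.p_value == pytest.approx(sp.pvalue, abs=1e-8)


def test_spearman_exact_p_agrees_with_scipy_enumeration():
    # scipy >= 1.9 permutation_test gives the exact reference for small n
    rng = np.random.default_rng(7)
    x = rng.standard_normal(6)
    y = rng.standard_normal(6)
    ours = spearman(x, y)

    def statistic(yy):
        return brute_spearman(x, yy)

    ref = st.permutation_test(
        (y,), statistic, permutation_type="pairings", n_resamples=np.inf,
        alternative="two-sided")
    assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_spearman_errors():
    with pytest.raises(ValueError):
        spearman([1, 2], [3, 4])
    with pytest.raises(ValueError):
        spearman([1, 1, 1, 1], [1, 2, 3, 4])


def test_spearman_pairwise_deletion():
    x = [1, 2, np.nan, 4, 5]
    y = [2, 3, 9, 5, np.nan]
    res = spearman(x, y)
    assert res.n == 3
    assert res.statistic == pytest.approx(1.0)


def test_kruskal_wallis_matches_brute_force_and_scipy():
    rng = np.random.default_rng(3)
    for _ in range(100):
        k = rng.integers(2, 5)
        groups = [rng.integers(0, 8, rng.integers(3, 8)).astype(float)
                  for _ in range(k)]
        if len(np.unique(np.concatenate(groups))) < 2:
            continue
        ours = kw_dunn(groups)
        assert ours.statistic == pytest.approx(brute_kruskal_h(groups),
                                               abs=1e-10)
        ref = st.kruskal(*groups)
        assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_kruskal_identical_data_degenerate():
    res = kw_dunn([[3.0, 3.0, 3.0], [3.0, 3.0, 3.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_dunn_z_matches_hand_computation():
    # no ties: z = (R1 - R2) / sqrt((N(N+1)/12)(1/n1 + 1/n2))
    g1 = [1.0, 2.0, 3.0, 4.0]
    g2 = [5.0, 6.0, 7.0, 8.0, 9.0]
    res = kw_dunn({"a": g1, "b": g2}, adjust="none")
    N = 9
    r1, r2 = np.mean([1, 2, 3, 4]), np.mean([5, 6, 7, 8, 9])
    z_expect = (r1 - r2) / np.sqrt(N * (N + 1) / 12 * (1 / 4 + 1 / 5))
    row = res.posthoc.iloc[0]
    assert row["z"] == pytest.approx(z_expect, abs=1e-12)
    assert row["p_raw"] == pytest.approx(2 * st.norm.sf(abs(z_expect)),
                                         abs=1e-12)


def test_dunn_separated_groups_significant():
    rng = np.random.default_rng(11)
    hits = 0
    for s in range(50):
        g = {k: rng.standard_normal(20) + 10.0 * i
             for i, k in enumerate("abc")}
        res = kw_dunn(g)
        if res.p_value < 0.001:
            hits += 1
    assert hits >= 50 * 0.99


def test_anova_two_groups_equals_t_squared():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a = rng.standard_normal(rng.integers(3, 10))
        b = rng.standard_normal(rng.integers(3, 10)) + 0.5
        res = anova_tukey([a, b])
        t = st.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p_value == pytest.approx(t.pvalue, rel=1e-8)


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(6)
    groups = [rng.standard_normal(8) + i for i in range(4)]
    res = anova_tukey(groups)
    ref = st.f_oneway(*groups)
    assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)


def test_tukey_matches_statsmodels():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(9)
    groups = {k: rng.standard_normal(10) + d
              for k, d in [("a", 0.0), ("b", 1.0), ("c", 3.0)]}
    res = anova_tukey(groups)
    data = np.concatenate(list(groups.values()))
    labels = np.repeat(list(groups.keys()), 10)
    ref = pairwise_tukeyhsd(data, labels)
    ours_p = res.posthoc.sort_values(["group_a", "group_b"])["p_adj"].to_numpy()
    assert np.allclose(ours_p, ref.pvalues, atol=1e-6)


def test_anova_identical_data_degenerate():
    res = anova_tukey([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_tukey_detects_planted_group_ordering():
    rng = np.random.default_rng(13)
    groups = {
        "corner": 0.10 + 0.002 * rng.standard_normal(4),
        "edge": 0.07 + 0.002 * rng.standard_normal(12),
        "interior": 0.04 + 0.002 * rng.standard_normal(9),
    }
    res = anova_tukey(groups)
    assert res.p_value < 1e-4
    ph = res.posthoc
    corner_pairs = ph[(ph["group_a"] == "corner") | (ph["group_b"] == "corner")]
    assert (corner_pairs["p_adj"] < 0.05).all()


def test_correlate_strain_metrics_excludes_screened_electrodes():
    import pandas as pd

    n = 30
    rng = np.random.default_rng(21)
    strain = np.linspace(0.01, 0.1, n)
    ring = np.tile([1, 2, 3], 10)
    table = pd.DataFrame({
        "electrode_id": np.arange(n),
        "avg_strain": strain,
        "ring_label": ring,
        "is_corner": np.zeros(n, bool),
    })
    imp = 1.0 - strain * 5 + 0.05 * rng.standard_normal(n)
    metrics = pd.DataFrame({
        "electrode_id": np.arange(n),
        "functional": [True] * (n - 5) + [False] * 5,
        "connected": [True] * n,
        "impedance_norm": imp,
    })
    rep = correlate_strain_metrics(table, metrics,
                                   metric_names=("impedance_norm",))
    res = rep["spearman"]["impedance_norm"]
    assert res.n == n - 5
    assert res.statistic < -0.8
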