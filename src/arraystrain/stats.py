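"""Rank statistics and the strain-vs-performance correlation report.

Spearman rank correlation (exact permutation p for small n), Kruskal-Wallis
with Dunn's post-hoc z-tests (Holm-adjusted by default; the raw z and p are
also reported), and one-way ANOVA with Tukey's HSD.  The report stage joins
a per-electrode strain table with the normalized metric table, excludes
screened-out and unconnected electrodes, and runs per-metric Spearman
correlations plus ring-group tests, with optional heatmap/violin figures.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = [
    "CorrelationResult",
    "spearman",
    "kw_dunn",
    "anova_tukey",
    "correlate_strain_metrics",
]


@dataclass
class CorrelationResult:
    """Container for one statistical test."""

    kind: str  # "spearman" | "kruskal_wallis" | "anova"
    statistic: float  # rho, H or F
    p_value: float
    n: int
    groups: list = field(default_factory=list)  # labels
    group_medians: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None  # pairwise table


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

def _rank(x: np.ndarray) -> np.ndarray:
    return st.rankdata(x, method="average")


@lru_cache(maxsize=8)
def _perm_cache(n: int) -> np.ndarray:
    """All permutations of range(n) as an (n!, n) array (n <= 9)."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def spearman(x, y, exact_max_n: int = 9) -> CorrelationResult:
    """Spearman rank-order correlation with two-sided p-value.

    Pairs with missing values are deleted.  Ties get average ranks.  For
    n <= ``exact_max_n`` the p-value comes from the exact permutation
    distribution of rho; otherwise from the t approximation
    t = rho sqrt((n-2)/(1-rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for constant input")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        perms = _perm_cache(n)
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        num = ryc @ rxc
        den = np.sqrt(np.sum(rxc**2) * np.sum(ryc**2, axis=1))
        rhos = num / den
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho**2))
            p = float(2 * st.t.sf(abs(t), df=n - 2))
    return CorrelationResult(kind="spearman", statistic=rho, p_value=p, n=n)


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank_, i in enumerate(order):
        running = max(running, (m - rank_) * p[i])
        adj[i] = min(1.0, running)
    return adj


def kw_dunn(groups: dict | list, adjust: str = "holm") -> CorrelationResult:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc z-tests.

    ``groups`` maps labels to 1-D samples (or is a list of samples).  The H
    statistic is tie-corrected; Dunn's z uses the pooled-rank variance
    N(N+1)/12 - tie correction, with two-sided normal p-values adjusted by
    Holm's method by default (``adjust="none"`` reports raw p only).
    All-identical data returns H = 0, p = 1.
    """
    if not isinstance(groups, dict):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    labels = list(groups.keys())
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    samples = [s[np.isfinite(s)] for s in samples]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    ns = np.array([len(s) for s in samples])
    N = int(ns.sum())
    if N < 5:
        raise ValueError("need at least 5 observations in total")
    pooled = np.concatenate(samples)
    ranks = _rank(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    split = np.cumsum(ns)[:-1]
    rank_groups = np.split(ranks, split)
    rbar = np.array([g.mean() for g in rank_groups])
    if np.all(counts == N) or np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H = (12.0 / (N * (N + 1))) * float(np.sum(ns * rbar**2)) \
            - 3.0 * (N + 1)
        ct = 1.0 - tie_sum / (N**3 - N)
        if ct <= 0:
            H, p = 0.0, 1.0
        else:
            H /= ct
            p = float(st.chi2.sf(H, df=len(samples) - 1))
    # Dunn pairwise
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        se = math.sqrt(var_base * (1.0 / ns[i] + 1.0 / ns[j]))
        z = (rbar[i] - rbar[j]) / se if se > 0 else 0.0
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": z, "p_raw": float(2 * st.norm.sf(abs(z)))})
    posthoc = pd.DataFrame(rows)
    if adjust == "holm" and len(posthoc):
        posthoc["p_adj"] = _holm(posthoc["p_raw"].to_numpy())
    elif len(posthoc):
        posthoc["p_adj"] = posthoc["p_raw"]
    medians = {k: float(np.median(s)) for k, s in zip(labels, samples)}
    return CorrelationResult(kind="kruskal_wallis", statistic=float(H),
                             p_value=p, n=N, groups=labels,
                             group_medians=medians, posthoc=posthoc)


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

def anova_tukey(groups: dict | list) -> CorrelationResult:
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    Degenerate all-identical data reports F = 0, p = 1.  Tukey p-values use
    the studentized-range distribution.
    """
    if not isinstance(groups, dict):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    labels = list(groups.keys())
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    samples = [s[np.isfinite(s)] for s in samples]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    ns = np.array([len(s) for s in samples])
    N = int(ns.sum())
    means = np.array([s.mean() for s in samples])
    grand = np.concatenate(samples).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((s - s.mean()) ** 2) for s in samples))
    df_b, df_w = len(samples) - 1, N - len(samples)
    if ss_within == 0 and ss_between == 0:
        F, p = 0.0, 1.0
        mse = 0.0
    else:
        mse = ss_within / df_w
        F = (ss_between / df_b) / mse if mse > 0 else np.inf
        p = float(st.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    rows = []
    for i, j in itertools.combinations(range(len(samples)), 2):
        diff = means[i] - means[j]
        se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j])) \
            if mse > 0 else 0.0
        if se > 0:
            q = abs(diff) / se
            pt = float(st.studentized_range.sf(q, len(samples), df_w))
        else:
            q, pt = (np.inf, 0.0) if diff != 0 else (0.0, 1.0)
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "diff": diff, "q": q, "p_adj": pt})
    medians = {k: float(np.median(s)) for k, s in zip(labels, samples)}
    return CorrelationResult(kind="anova", statistic=float(F), p_value=p,
                             n=N, groups=labels, group_medians=medians,
                             posthoc=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def correlate_strain_metrics(strain_table: pd.DataFrame,
                             metrics: pd.DataFrame,
                             metric_names: tuple = ("impedance_norm",
                                                    "ptpv_norm", "snr_norm",
                                                    "neighbor_corr_norm",
                                                    "evoked_snr_norm"),
                             array_column: str | None = None,
                             out_dir=None) -> dict:
    """Correlate per-electrode ROI strains with normalized metrics.

    ``strain_table`` must carry electrode_id, avg_strain, ring_label,
    is_corner (the ROI summary); ``metrics`` the normalized epoch table.
    Electrodes failing the screening or connectivity masks are excluded.
    Returns a dict with per-metric Spearman results (pooled and per array
    when ``array_column`` is given), ring-group Kruskal-Wallis + Dunn
    results, and writes CSV/PNG artifacts when ``out_dir`` is given.
    """
    merged = strain_table.merge(metrics, on="electrode_id",
                                suffixes=("", "_m"))
    conn = merged.get("connected_m", merged.get("connected", True))
    keep = merged["functional"].fillna(False).astype(bool) \
        & pd.Series(conn).fillna(False).astype(bool)
    merged = merged[keep]
    report: dict = {"spearman": {}, "spearman_per_array": {},
                    "ring_tests": {}, "n_electrodes": int(len(merged))}
    for m in metric_names:
        if m not in merged.columns:
            continue
        sub = merged[np.isfinite(merged[m])]
        if len(sub) < 3:
            report["spearman"][m] = None
            continue
        res = spearman(sub["avg_strain"], sub[m])
        report["spearman"][m] = res
        if array_column and array_column in merged.columns:
            per = {}
            for arr_id, g in sub.groupby(array_column):
                if len(g) >= 3:
                    per[arr_id] = spearman(g["avg_strain"], g[m])
            report["spearman_per_array"][m] = per
        # ring-group comparison of the metric (corner split out)
        lab = np.where(sub["is_corner"], "corner",
                       "ring" + sub["ring_label"].astype(str))
        groups = {k: sub[m].to_numpy()[lab == k] for k in np.unique(lab)}
        groups = {k: v for k, v in groups.items() if len(v) > 0}
        if len(groups) >= 2 and sum(len(v) for v in groups.values()) >= 5:
            try:
                report["ring_tests"][m] = kw_dunn(groups)
            except ValueError:
                report["ring_tests"][m] = None
    if out_dir is not None:
        _write_report(merged, report, metric_names, out_dir)
    return report


def _write_report(merged: pd.DataFrame, report: dict, metric_names,
                  out_dir) -> None:
    import json
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    merged.to_csv(out / "strain_metrics_merged.csv", index=False)
    summary = {}
    for m, res in report["spearman"].items():
        if res is not None:
            summary[m] = {"rho": res.statistic, "p": res.p_value, "n": res.n}
    (out / "spearman.json").write_text(json.dumps(summary, indent=2))
    rows = int(merged["row"].max()) + 1 if "row" in merged else None
    for m in metric_names:
        if m not in merged.columns:
            continue
        res = report["spearman"].get(m)
        fig, axes = plt.subplots(1, 3 if rows else 2,
                                 figsize=(12 if rows else 8, 3.2))
        k = 0
        if rows:
            cols = int(merged["col"].max()) + 1
            grid = np.full((rows, cols), np.nan)
            for _, r in merged.iterrows():
                grid[int(r["row"]), int(r["col"])] = r[m]
            im = axes[k].imshow(grid, cmap="viridis")
            fig.colorbar(im, ax=axes[k], shrink=0.8)
            axes[k].set_title(f"{m} heatmap")
            k += 1
        lab = np.where(merged["is_corner"], "corner",
                       "ring" + merged["ring_label"].astype(str))
        data, names = [], []
        for g in np.unique(lab):
            v = merged[m].to_numpy()[lab == g]
            v = v[np.isfinite(v)]
            if len(v):
                data.append(v)
                names.append(g)
        if data:
            axes[k].violinplot(data, showmedians=True)
            axes[k].set_xticks(range(1, len(names) + 1), names,
                               rotation=45, fontsize=7)
            axes[k].set_title("by ring group")
        k += 1
        ok = np.isfinite(merged[m])
        axes[k].plot(merged["avg_strain"][ok], merged[m][ok], "o", ms=3)
        if res is not None:
            axes[k].set_title(f"rho={res.statistic:.2f} p={res.p_value:.2g}")
        axes[k].set_xlabel("ROI average strain")
        axes[k].set_ylabel(m)
        fig.tight_layout()
        fig.savefig(out / f"{m}.png", dpi=110)
        plt.close(fig)
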