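"""Group-level statistics: descriptives, normality-gated comparisons with
post-hoc tests, two-way ring-by-group ANOVA, and Spearman correlation.

The comparison battery mirrors common practice in quantitative histology:
Shapiro-Wilk decides per group between one-way ANOVA with Tukey's HSD
(all groups normal) and Kruskal-Wallis with Bonferroni-adjusted Dunn
post-hoc tests (any group non-normal). Alpha is 0.05 throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

ALPHA = 0.05
#: largest pooled sample size for which Kruskal-Wallis uses the exact
#: permutation null instead of the chi-square approximation
EXACT_KW_MAX_N = 12


@dataclass
class GroupSample:
    group_label: str
    values: np.ndarray
    level: str = "region"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        self.values = v[np.isfinite(v)]


@dataclass
class PairwiseResult:
    group_a: str
    group_b: str
    adjusted_p: float


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    pairwise: list[PairwiseResult] = field(default_factory=list)
    shapiro_p: dict[str, float] = field(default_factory=dict)
    factors: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


# ---------------------------------------------------------------------------
# descriptives


def descriptive(values) -> dict[str, float]:
    """Mean, SD (n-1), median, mode (smallest on ties), extremes,
    quartiles with linear interpolation, IQR and Tukey fences."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("descriptive statistics need at least one finite value")
    uniq, counts = np.unique(v, return_counts=True)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "median": float(np.median(v)),
        "mode": float(uniq[np.argmax(counts)]),
        "min": float(v.min()),
        "max": float(v.max()),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "fence_low": float(q1 - 1.5 * iqr),
        "fence_high": float(q3 + 1.5 * iqr),
    }


# ---------------------------------------------------------------------------
# Kruskal-Wallis (with exact small-sample option) and Dunn post-hoc


def _kw_statistic(ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    n = ranks.size
    h = 0.0
    start = 0
    for m in sizes:
        r = ranks[start:start + m]
        h += r.sum() ** 2 / m
        start += m
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    return h / tie_term if tie_term > 0 else 0.0


def _tie_correction(values: np.ndarray) -> float:
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - (counts**3 - counts).sum() / (n**3 - n)


def kruskal_wallis(groups: list[np.ndarray], method: str = "auto") -> tuple[float, float]:
    """Kruskal-Wallis H and p; exact permutation p for small pooled n.

    ``method``: "auto" (exact when pooled n <= 12), "exact", or "asymptotic".
    """
    pooled = np.concatenate(groups)
    n = pooled.size
    sizes = [len(g) for g in groups]
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    tie = _tie_correction(pooled)
    ranks = stats.rankdata(pooled)
    h_obs = _kw_statistic(ranks, sizes, tie)
    exact = method == "exact" or (method == "auto" and n <= EXACT_KW_MAX_N)
    if not exact:
        return h_obs, float(stats.chi2.sf(h_obs, len(groups) - 1))
    # enumerate all distinct assignments of rank positions to groups
    hits = 0
    total = 0
    idx_all = frozenset(range(n))

    def recurse(remaining: frozenset, gi: int, chosen_ranks: list[np.ndarray]):
        nonlocal hits, total
        if gi == len(sizes) - 1:
            last = ranks[sorted(remaining)]
            h = _kw_statistic(np.concatenate(chosen_ranks + [last]), sizes, tie)
            total += 1
            if h >= h_obs - 1e-12:
                hits += 1
            return
        for combo in itertools.combinations(sorted(remaining), sizes[gi]):
            recurse(remaining - set(combo), gi + 1, chosen_ranks + [ranks[list(combo)]])

    recurse(idx_all, 0, [])
    return h_obs, hits / total


def dunn_posthoc(groups: list[np.ndarray], labels: list[str]) -> list[PairwiseResult]:
    """Dunn's rank-based pairwise z tests, Bonferroni-adjusted."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1))
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        start += len(g)
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for (i, j) in itertools.combinations(range(len(groups)), 2):
        var = (n * (n + 1) / 12.0 - tie_term) * (1.0 / len(groups[i]) + 1.0 / len(groups[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var) if var > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
        out.append(PairwiseResult(labels[i], labels[j], float(p)))
    return out


# ---------------------------------------------------------------------------
# omnibus group comparison


def _as_groups(samples) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(samples, dict):
        samples = [GroupSample(k, v) for k, v in samples.items()]
    labels = [s.group_label for s in samples]
    values = [np.asarray(s.values, dtype=float) for s in samples]
    return labels, values


def compare_groups(samples, alpha: float = ALPHA, kw_method: str = "auto") -> TestResult:
    """Shapiro-gated omnibus comparison with post-hoc pairwise tests.

    All groups normal (Shapiro-Wilk p > alpha): one-way ANOVA + Tukey HSD.
    Any group non-normal: Kruskal-Wallis + Dunn (Bonferroni).
    """
    labels, groups = _as_groups(samples)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for lab, g in zip(labels, groups):
        if len(g) < 3:
            raise ValueError(f"group {lab!r} has n={len(g)} < 3")
    shapiro_p = {}
    for lab, g in zip(labels, groups):
        if np.all(g == g[0]):
            shapiro_p[lab] = 0.0  # a constant sample is not normal
        else:
            shapiro_p[lab] = float(stats.shapiro(g).pvalue)
    all_normal = all(p > alpha for p in shapiro_p.values())
    pooled = np.concatenate(groups)
    label_vec = np.concatenate([[lab] * len(g) for lab, g in zip(labels, groups)])

    if all_normal:
        f, p = stats.f_oneway(*groups)
        tk = pairwise_tukeyhsd(pooled, label_vec, alpha=alpha)
        pairs = [
            PairwiseResult(str(a), str(b), float(pv))
            for (a, b), pv in zip(itertools.combinations(tk.groupsunique, 2), tk.pvalues)
        ]
        return TestResult("anova_oneway", float(f), float(p), pairs, shapiro_p)
    h, p = kruskal_wallis(groups, method=kw_method)
    pairs = dunn_posthoc(groups, labels)
    return TestResult("kruskal_wallis", float(h), float(p), pairs, shapiro_p)


def two_way_ring_analysis(obs: pd.DataFrame, value_col: str = "value",
                          group_col: str = "group", ring_col: str = "ring") -> TestResult:
    """Fixed-effects two-way ANOVA (group x ring) with interaction.

    Uses Sum-coded factors with type-III partial sums of squares, valid for
    the unbalanced region counts this design always produces; Tukey HSD
    pairwise comparisons are reported per factor.
    """
    df = obs[[value_col, group_col, ring_col]].dropna().copy()
    df.columns = ["value", "group", "ring"]
    df["ring"] = df["ring"].astype(str)
    cells = df.groupby(["group", "ring"]).size()
    expected = list(itertools.product(df["group"].unique(), df["ring"].unique()))
    missing = [c for c in expected if c not in cells.index]
    if missing:
        raise ValueError(f"empty design cells: {missing}")
    if np.all(df["value"].to_numpy() == df["value"].iloc[0]):
        factors = {k: {"F": 0.0, "p": 1.0} for k in ("group", "ring", "interaction")}
        return TestResult("anova_twoway", 0.0, 1.0, factors=factors)
    model = ols("value ~ C(group, Sum) * C(ring, Sum)", data=df).fit()
    table = anova_lm(model, typ=3)
    key_map = {
        "C(group, Sum)": "group",
        "C(ring, Sum)": "ring",
        "C(group, Sum):C(ring, Sum)": "interaction",
    }
    factors = {
        key_map[k]: {"F": float(table.loc[k, "F"]), "p": float(table.loc[k, "PR(>F)"])}
        for k in key_map if k in table.index
    }
    pairs = []
    for factor in ("group", "ring"):
        if df[factor].nunique() < 2:
            continue
        tk = pairwise_tukeyhsd(df["value"].to_numpy(), df[factor].to_numpy())
        pairs += [
            PairwiseResult(f"{factor}:{a}", f"{factor}:{b}", float(pv))
            for (a, b), pv in zip(itertools.combinations(tk.groupsunique, 2), tk.pvalues)
        ]
    g = factors["group"]
    return TestResult("anova_twoway", g["F"], g["p"], pairs, factors=factors)


# ---------------------------------------------------------------------------
# Spearman correlation with Fisher-z interval


def spearman_with_ci(x, y, confidence: float = 0.95) -> CorrelationResult:
    """Spearman rho with a Fisher-z confidence interval.

    The interval uses SE = sqrt(1.06 / (n - 3)) on the z scale; the p-value
    comes from the t approximation t = rho * sqrt((n-2) / (1-rho^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant input")
    rho = float(stats.spearmanr(x, y).statistic)
    zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    z = np.arctanh(rho_c)
    se = math.sqrt(1.06 / (n - 3))
    ci_low, ci_high = float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, ci_low, ci_high, p, n)
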