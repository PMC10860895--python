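"""Gated univariate statistics and Pearson correlation screens.

Per-variable group comparisons follow a two-stage gate: every group is
checked for normality (Lilliefors-corrected Kolmogorov-Smirnov by
default) and the groups jointly for homogeneity of variance (Levene).
If both pass at alpha the variable is analysed by one-way ANOVA with
Tukey HSD post hoc; otherwise by Kruskal-Wallis with Dunn's test and
Bonferroni correction.  Pairwise outcomes are summarised as a compact
letter display (groups sharing a letter are not significantly
different).  Correlation screens are plain Pearson tests with
0.05/0.01/0.001 significance stars and no multiplicity adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupedData",
    "StatTestResult",
    "gate_test",
    "kruskal_wallis",
    "dunn_bonferroni",
    "anova_tukey",
    "pearson",
    "correlation_screen",
    "compact_letters",
]


@dataclass
class GroupedData:
    """A real-valued variable observed across >= 2 groups."""

    values: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != self.groups.shape:
            raise ValueError("values and groups must align")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value: str, group: str) -> "GroupedData":
        return cls(df[value].to_numpy(), df[group].to_numpy())

    def split(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for g in pd.unique(self.groups):
            out[str(g)] = self.values[self.groups == g]
        return out

    def check(self, min_n: int = 2) -> dict[str, np.ndarray]:
        by = self.split()
        if len(by) < 2:
            raise ValueError("need >= 2 groups")
        for g, v in by.items():
            if len(v) < min_n:
                raise ValueError(f"group {g!r} has fewer than {min_n} observations")
        return by


@dataclass
class StatTestResult:
    test: str
    statistic: float
    df: tuple[float, ...] | float
    p_value: float
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    letters: dict[str, str] = field(default_factory=dict)
    branch: str = ""
    gate: dict[str, float] = field(default_factory=dict)


def compact_letters(
    groups: list[str], sig_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Starts from one block holding every group; each significantly
    different pair splits the blocks that contain both; blocks fully
    contained in another are absorbed.  Groups share a letter iff no
    significant difference separates them.
    """
    blocks: list[set[str]] = [set(groups)]
    for pair in sorted(sig_pairs, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        new_blocks: list[set[str]] = []
        for blk in blocks:
            if a in blk and b in blk:
                new_blocks.append(blk - {a})
                new_blocks.append(blk - {b})
            else:
                new_blocks.append(blk)
        # absorb blocks contained in another
        blocks = []
        for blk in new_blocks:
            if not blk:
                continue
            if any(blk < other for other in new_blocks if other is not blk):
                continue
            if blk in blocks:
                continue
            blocks.append(blk)
    blocks.sort(key=lambda blk: min(groups.index(g) for g in blk))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, blk in enumerate(blocks):
        for g in groups:
            if g in blk:
                letters[g] += alphabet[i % len(alphabet)]
    return letters


def kruskal_wallis(data: GroupedData) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    by = data.check()
    if np.ptp(data.values) == 0:  # one shared value everywhere
        return 0.0, 1.0
    H, p = sps.kruskal(*by.values())
    return float(H), float(p)


def dunn_bonferroni(data: GroupedData, alpha: float = 0.05) -> StatTestResult:
    """Dunn's rank-based post-hoc comparisons with Bonferroni correction.

    Pairwise z statistics use pooled mean ranks with the tie-corrected
    variance; adjusted p = min(1, m * p) with m = k(k-1)/2.
    """
    by = data.check()
    names = list(by.keys())
    k = len(names)
    N = len(data.values)
    ranks = sps.rankdata(data.values)
    mean_ranks = {g: ranks[data.groups == g_raw].mean()
                  for g, g_raw in zip(names, pd.unique(data.groups))}
    sizes = {g: len(v) for g, v in by.items()}
    _, tie_counts = np.unique(data.values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1)))
    m = k * (k - 1) // 2
    rows = []
    sig = set()
    for a, b in itertools.combinations(names, 2):
        var = (N * (N + 1) / 12.0 - tie_term) * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, m * p)
        rows.append({"group_a": a, "group_b": b, "statistic": z,
                     "p_raw": p, "p_adj": p_adj})
        if p_adj < alpha:
            sig.add(frozenset((a, b)))
    H, p_omni = kruskal_wallis(data)
    return StatTestResult(
        test="kruskal-dunn-bonferroni",
        statistic=H,
        df=float(k - 1),
        p_value=p_omni,
        pairwise=pd.DataFrame(rows),
        letters=compact_letters(names, sig),
        branch="nonparametric",
    )


def anova_tukey(data: GroupedData, alpha: float = 0.05) -> StatTestResult:
    """One-way ANOVA with Tukey HSD post hoc and a letter display."""
    by = data.check()
    names = list(by.keys())
    samples = [by[g] for g in names]
    k = len(names)
    N = len(data.values)
    if all(np.ptp(s) == 0 for s in samples):
        means = [s.mean() for s in samples]
        if np.ptp(means) == 0:
            F, p = 0.0, 1.0
        else:  # zero within-group variance, unequal means: perfect separation
            F, p = np.inf, 0.0
        sig = (set() if p == 1.0 else
               {frozenset((a, b)) for a, b in itertools.combinations(names, 2)
                if by[a].mean() != by[b].mean()})
        rows = [{"group_a": a, "group_b": b, "statistic": np.nan,
                 "p_raw": 1.0 if frozenset((a, b)) not in sig else 0.0,
                 "p_adj": 1.0 if frozenset((a, b)) not in sig else 0.0}
                for a, b in itertools.combinations(names, 2)]
        return StatTestResult(
            test="anova-tukey", statistic=float(F), df=(k - 1, N - k),
            p_value=float(p), pairwise=pd.DataFrame(rows),
            letters=compact_letters(names, sig), branch="parametric",
        )
    F, p = sps.f_oneway(*samples)
    if np.ptp(data.values) == 0:
        F, p = 0.0, 1.0
    hsd = sps.tukey_hsd(*samples)
    rows = []
    sig = set()
    for i, j in itertools.combinations(range(k), 2):
        padj = float(hsd.pvalue[i, j])
        rows.append({"group_a": names[i], "group_b": names[j],
                     "statistic": float(hsd.statistic[i, j]),
                     "p_raw": padj, "p_adj": padj})
        if padj < alpha:
            sig.add(frozenset((names[i], names[j])))
    return StatTestResult(
        test="anova-tukey",
        statistic=float(F),
        df=(k - 1, N - k),
        p_value=float(p),
        pairwise=pd.DataFrame(rows),
        letters=compact_letters(names, sig),
        branch="parametric",
    )


def gate_test(
    data: GroupedData,
    alpha: float = 0.05,
    normality: str = "lilliefors",
    levene_center: str = "mean",
) -> StatTestResult:
    """Normality/homogeneity gate choosing the parametric branch or not.

    Every group must pass a KS-type normality test (Lilliefors by
    default, naive KS against the fitted normal with ``normality="ks"``)
    and Levene's test (mean-centred classic form; ``levene_center=
    "median"`` gives Brown-Forsythe) at ``alpha`` for the variable to
    be analysed by ANOVA + Tukey; otherwise Kruskal-Wallis + Dunn.
    """
    by = data.check()
    gate: dict[str, float] = {}
    normal = True
    for g, v in by.items():
        if np.ptp(v) == 0:
            p_norm = 0.0  # degenerate: constant group is not Gaussian
        elif len(v) < 4:
            p_norm = 0.0  # too small to test normality: stay nonparametric
        elif normality == "lilliefors":
            _, p_norm = lilliefors(v, dist="norm")
        elif normality == "ks":
            _, p_norm = sps.kstest(v, "norm", args=(v.mean(), v.std(ddof=1)))
        else:
            raise ValueError(f"unknown normality test {normality!r}")
        gate[f"normality_p[{g}]"] = float(p_norm)
        normal &= p_norm > alpha
    try:
        _, p_lev = sps.levene(*by.values(), center=levene_center)
    except ValueError:
        p_lev = 1.0
    gate["levene_p"] = float(p_lev)
    homogeneous = p_lev > alpha
    if normal and homogeneous:
        res = anova_tukey(data, alpha=alpha)
    else:
        res = dunn_bonferroni(data, alpha=alpha)
    res.gate = gate
    return res


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment r with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector has no defined correlation")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def correlation_screen(
    table: pd.DataFrame, focal: str, partners: list[str] | None = None
) -> pd.DataFrame:
    """One Pearson test of ``focal`` against each partner column.

    No multiplicity adjustment is applied; significance is reported as
    stars at 0.05 / 0.01 / 0.001.  The focal column itself is excluded.
    """
    if focal not in table.columns:
        raise KeyError(f"focal column {focal!r} missing from table")
    if partners is None:
        partners = [c for c in table.columns if c != focal]
    orphans = [c for c in partners if c not in table.columns]
    if orphans:
        raise KeyError(f"partner columns missing from table: {orphans}")
    rows = []
    for c in partners:
        if c == focal:
            continue
        r, p = pearson(table[focal], table[c])
        rows.append({"focal": focal, "partner": c, "r": r, "p": p,
                     "stars": _stars(p), "n": len(table)})
    return pd.DataFrame(rows)
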