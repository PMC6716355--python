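"""Alpha diversity (Shannon, ACE) and two-group comparisons.

Shannon uses the natural log (mothur convention; base is configurable).  ACE
is the standard abundance-based coverage estimator with rare cutoff 10.
Group contrasts are two-sided Welch t-tests, with Benjamini-Hochberg
adjustment across pairwise comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable


def shannon(counts: Sequence[float] | np.ndarray, base: float | None = None) -> float:
    """Shannon entropy H = -sum p_i log p_i over nonzero proportions."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def observed_richness(counts: Sequence[float] | np.ndarray) -> int:
    return int((np.asarray(counts) > 0).sum())


def chao1(counts: Sequence[float] | np.ndarray) -> float:
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(len(c) + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ace(counts: Sequence[float] | np.ndarray, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Splits taxa at ``rare_cutoff``: abundant taxa are counted as-is, rare
    taxa are corrected by the sample coverage C_ace = 1 - F1/N_rare and the
    rare-taxon coefficient of variation gamma^2 (floored at 0).  Falls back
    to the observed richness when there are no rare taxa and to Chao1 when
    every rare taxon is a singleton (C_ace = 0).
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        return chao1(np.asarray(counts, dtype=float))
    ssum = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = max(
        s_rare / c_ace * ssum / (n_rare * (n_rare - 1.0)) - 1.0 if n_rare > 1 else 0.0,
        0.0,
    )
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Welch t-test: returns (t, df, p).

    Degenerate zero-variance inputs with unequal means yield a p-value at
    the machine floor, with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        warnings.warn("zero within-group variance with unequal means; p at machine floor")
        return float(np.inf), float(a.size + b.size - 2), float(np.nextafter(0, 1))
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def alpha_diversity(table: OtuTable, rare_cutoff: int = 10, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon, ACE and observed-OTU table."""
    rows = []
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        rows.append(
            {
                "sample_id": sample,
                "shannon": shannon(col, base=base),
                "ace": ace(col, rare_cutoff=rare_cutoff),
                "observed_otus": observed_richness(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_groups(
    values: Mapping[str, float] | pd.Series, groups: Mapping[str, str] | pd.Series, index: str = ""
) -> pd.DataFrame:
    """All pairwise Welch t-tests between groups, BH-adjusted.

    ``values`` maps sample -> index value, ``groups`` maps sample -> group
    label; groups with fewer than two samples are skipped with a warning.
    """
    values = pd.Series(values)
    groups = pd.Series(groups).reindex(values.index)
    by_group = {g: values[groups == g].to_numpy() for g in sorted(groups.dropna().unique())}
    usable = {g: v for g, v in by_group.items() if v.size >= 2}
    skipped = sorted(set(by_group) - set(usable))
    if skipped:
        warnings.warn(f"groups with n < 2 skipped: {skipped}")
    rows = []
    for ga, gb in itertools.combinations(sorted(usable), 2):
        t, df, p = welch_t(usable[ga], usable[gb])
        rows.append({"group_a": ga, "group_b": gb, "index": index, "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "index", "t", "df", "p"])
    if len(out):
        out["p_adj"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    else:
        out["p_adj"] = []
    return out
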