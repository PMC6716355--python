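"""Co-occurrence networks over abundant OTUs via Spearman correlation.

Edges connect pairs among the top-k most abundant OTUs whose rank
correlation across samples is strong (|rho| >= 0.75 by default; the
convention follows figure legends where the threshold is printed against the
correlation coefficient) and significant (p < 0.05, no multiple-testing
correction unless requested).  Correlations are computed on per-sample
relative abundances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Midrank Spearman rho with a two-sided t-approximation p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors differ in length")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero-variance vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def top_k(table: OtuTable, k: int = 20) -> list[str]:
    """The k OTUs with the highest total count (ties by id)."""
    totals = table.counts.sum(axis=1)
    order = sorted(table.otu_ids, key=lambda i: (-totals[i], i))
    if len(order) < k:
        warnings.warn(f"table has only {len(order)} OTUs (< k={k}); returning all")
        return order
    return order[:k]


@dataclass(frozen=True)
class NetworkEdge:
    otu_a: str
    otu_b: str
    rho: float
    p: float

    def __post_init__(self) -> None:
        if self.otu_a >= self.otu_b:
            raise ValueError("edges must be canonically ordered (otu_a < otu_b)")

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


def build_network(
    table: OtuTable,
    k: int = 20,
    rho_threshold: float = 0.75,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[NetworkEdge]:
    """Score all pairs among the top-k OTUs; emit strong significant edges.

    Works on relative abundances.  Pairs involving a zero-variance OTU are
    skipped with a warning.  With ``bh_correct`` the p-values are
    Benjamini-Hochberg adjusted before the alpha cut.
    """
    if len(table.sample_ids) < 4:
        raise ValueError("need at least 4 samples")
    rel = table.relative_abundance()
    nodes = top_k(table, k)
    candidates = []
    skipped = 0
    for a, b in itertools.combinations(sorted(nodes), 2):
        va, vb = rel.loc[a].to_numpy(), rel.loc[b].to_numpy()
        if np.all(va == va[0]) or np.all(vb == vb[0]):
            skipped += 1
            continue
        rho, p = spearman(va, vb)
        candidates.append((a, b, rho, p))
    if skipped:
        warnings.warn(f"skipped {skipped} pairs with a zero-variance OTU")
    if not candidates:
        return []
    pvals = np.array([c[3] for c in candidates])
    if bh_correct:
        pvals = stats.false_discovery_control(pvals, method="bh")
    edges = [
        NetworkEdge(a, b, rho, float(p_adj))
        for (a, b, rho, _), p_adj in zip(candidates, pvals)
        if abs(rho) >= rho_threshold and p_adj < alpha
    ]
    return edges


def edges_to_frame(edges: Sequence[NetworkEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.otu_a, e.otu_b, e.rho, e.p, e.sign) for e in edges],
        columns=["otu_a", "otu_b", "rho", "p", "sign"],
    )


def write_sif(edges: Sequence[NetworkEdge], path: str | Path) -> None:
    """SIF export for graph viewers: 'a cooccurs_pos|cooccurs_neg b'."""
    with open(path, "w") as fh:
        for e in edges:
            rel = "cooccurs_pos" if e.sign == "positive" else "cooccurs_neg"
            fh.write(f"{e.otu_a}\t{rel}\t{e.otu_b}\n")


def to_networkx(edges: Sequence[NetworkEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.otu_a, e.otu_b, rho=e.rho, p=e.p, sign=e.sign)
    return g


def intersect_edges(*edge_sets: Sequence[NetworkEdge]) -> list[NetworkEdge]:
    """Edges (same pair, same sign) present in at least two of the given
    per-group networks — an optional consensus post-step."""
    seen: dict[tuple[str, str, str], list[NetworkEdge]] = {}
    for edges in edge_sets:
        for e in edges:
            seen.setdefault((e.otu_a, e.otu_b, e.sign), []).append(e)
    out = [v[0] for v in seen.values() if len(v) >= 2]
    return sorted(out, key=lambda e: (e.otu_a, e.otu_b))
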