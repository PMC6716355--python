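"""Community ordination: Hellinger transform, Bray-Curtis, NMDS, ANOSIM.

NMDS minimises Kruskal stress-1 with primary treatment of ties: disparities
are the pool-adjacent-violators monotone regression of the configuration
distances on the observed dissimilarity order, and the configuration is
updated by Guttman-transform (SMACOF) steps.  Several random starts plus a
classical-scaling start are tried and the lowest-stress solution returned,
vegan-compatible semantics without claiming numerical equality.

ANOSIM is the rank-based R statistic with a label-permutation p-value
p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import isotonic_regression

from .tables import OtuTable


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # square symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("nonzero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(df.index.astype(str)), values=df.to_numpy(dtype=float))


def hellinger(table: OtuTable | pd.DataFrame) -> pd.DataFrame:
    """Square root of relative abundances; rows (samples) get unit L2 norm.

    Accepts an OtuTable (features x samples) or a samples x features frame;
    returns samples x features.
    """
    if isinstance(table, OtuTable):
        mat = table.counts.T
    else:
        mat = table
    totals = mat.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(f"zero-total samples: {list(totals.index[totals <= 0])}")
    return np.sqrt(mat.div(totals, axis=0))


def bray_curtis(matrix: pd.DataFrame) -> DissimilarityMatrix:
    """Pairwise Bray-Curtis: d(j,k) = sum|x_j - x_k| / sum(x_j + x_k).

    ``matrix`` is samples x features with non-negative entries.
    """
    x = matrix.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("negative entries")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if len(zero_rows) >= 2:
        raise ValueError(
            f"Bray-Curtis undefined between all-zero samples: "
            f"{[matrix.index[i] for i in zero_rows]}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return DissimilarityMatrix(ids=list(matrix.index.astype(str)), values=d)


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float
    n_starts: int
    converged: bool
    best_start: int
    stress_trace: list[float]  # per-iteration stress of the winning start


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson double-centering start configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)


def _stress_and_disparities(
    dist: np.ndarray, order: np.ndarray, inverse: np.ndarray
) -> tuple[float, np.ndarray]:
    """Kruskal stress-1 and PAV-fitted disparities for the current distances."""
    fitted_sorted = isotonic_regression(dist[order])
    dhat = fitted_sorted[inverse]
    denom = float((dist**2).sum())
    if denom == 0.0:
        return 0.0, dhat
    stress = float(np.sqrt(((dist - dhat) ** 2).sum() / denom))
    return stress, dhat


def nmds(
    d: DissimilarityMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | None = 0,
) -> NmdsResult:
    """Non-metric MDS of a dissimilarity matrix into k dimensions.

    Start 0 is classical scaling of the dissimilarities; the remaining
    ``n_starts - 1`` starts are seeded random configurations.  Within a
    start, SMACOF (Guttman-transform) updates alternate with monotone
    regression until the relative stress change drops below ``tol`` or
    ``max_iter`` is hit; the lowest-stress start is reported.
    """
    n = d.n
    if k >= n:
        raise ValueError(f"k={k} requires more than {k} samples")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    delta = d.condensed()
    # primary tie treatment: sort pairs by (delta, current distance) would
    # re-sort each iteration; we fix the order by delta with a stable sort,
    # which leaves tied blocks free for PAV to average
    order = np.argsort(delta, kind="stable")
    inverse = np.empty_like(order)
    inverse[order] = np.arange(order.size)
    rng = np.random.default_rng(seed)

    best: tuple | None = None
    for start in range(n_starts):
        if start == 0:
            x = _classical_scaling(d.values, k)
            if x.shape[1] < k:  # degenerate: pad with zeros
                x = np.hstack([x, np.zeros((n, k - x.shape[1]))])
        else:
            x = rng.normal(size=(n, k))
        x = x - x.mean(axis=0)
        dist = pdist(x)
        stress, dhat = _stress_and_disparities(dist, order, inverse)
        trace = [stress]
        converged = False
        for _ in range(max_iter):
            if stress == 0.0:
                converged = True
                break
            # Guttman transform with unit weights
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dist > 0, dhat / dist, 0.0)
            b = squareform(-ratio)
            np.fill_diagonal(b, squareform(ratio, checks=False).sum(axis=1))
            x = b @ x / n
            x = x - x.mean(axis=0)
            dist = pdist(x)
            new_stress, dhat = _stress_and_disparities(dist, order, inverse)
            trace.append(new_stress)
            if stress > 0 and abs(stress - new_stress) / stress < tol:
                stress = new_stress
                converged = True
                break
            stress = new_stress
        if best is None or stress < best[0]:
            best = (stress, x, converged, start, trace)

    stress, x, converged, start, trace = best
    coords = pd.DataFrame(x, index=d.ids, columns=[f"NMDS{i + 1}" for i in range(k)])
    return NmdsResult(
        coordinates=coords, stress=stress, n_starts=n_starts, converged=converged,
        best_start=start, stress_trace=trace,
    )


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"R": self.r, "p": self.p, "n_permutations": self.n_permutations}, indent=2
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def anosim(
    d: DissimilarityMatrix,
    groups: Mapping[str, str] | Sequence[str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = 0,
) -> AnosimResult:
    """Analysis of similarities on a dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 and midranks for ties; the p-value counts label
    permutations whose R reaches the observed one.
    """
    if isinstance(groups, Mapping) or isinstance(groups, pd.Series):
        labels = np.asarray([dict(groups)[i] for i in d.ids])
    else:
        labels = np.asarray(list(groups))
        if labels.size != d.n:
            raise ValueError("groups length does not match matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = list(uniq[counts < 2])
        raise ValueError(f"groups of size 1: {small}")

    ranks = rankdata(d.condensed())
    m = ranks.size
    iu, ju = np.triu_indices(d.n, k=1)

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu] == lab[ju]
        return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    # vectorized permutations: same-group masks for all permuted labelings
    perm_idx = np.array([rng.permutation(d.n) for _ in range(n_perm)])
    lab_codes = np.searchsorted(uniq, labels)
    perms = lab_codes[perm_idx]  # (n_perm, n)
    within = perms[:, iu] == perms[:, ju]  # (n_perm, m)
    n_within = within.sum(axis=1)
    sum_within = within @ ranks
    total = ranks.sum()
    mean_w = sum_within / n_within
    mean_b = (total - sum_within) / (m - n_within)
    r_perm = (mean_b - mean_w) / (m / 2.0)
    p = float((1 + int((r_perm >= r_obs - 1e-12).sum())) / (1 + n_perm))
    return AnosimResult(r=r_obs, p=p, n_permutations=n_perm)
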