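"""LEfSe-style biomarker discovery: Kruskal-Wallis screen + LDA effect size.

Features (OTUs or collapsed taxa) are scaled to per-million relative
abundances so effect sizes land on the familiar log10 scale where the
conventional threshold 4.0 is meaningful.  Features passing a Kruskal-Wallis
screen across classes are scored by a bootstrapped one-axis linear
discriminant: per bootstrap and class pair, the discriminant direction is
the regularised within-class-covariance solve of the class-mean difference,
(rescaled so its largest loading is 1), and a feature's effect is the
average of its discriminant-weighted mean difference |w_f * dmu_f| and its
raw mean difference |dmu_f|.  The score is
log10(mean bootstrap effect, floored at 1).  No subclass (within-class)
stage is applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """Midrank-corrected Kruskal-Wallis H and its chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.size != groups.size:
        raise ValueError("values and groups differ in length")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    samples = [values[groups == g] for g in uniq]
    if any(s.size == 0 for s in samples):
        raise ValueError("empty group")
    if values.size < 3:
        raise ValueError("need total n >= 3")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def to_per_million(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale a samples x features matrix to per-million per sample."""
    totals = matrix.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(f"zero-total samples: {list(totals.index[totals <= 0])}")
    return matrix.div(totals, axis=0) * 1e6


def lda_effect_size(
    matrix: pd.DataFrame,
    classes: Mapping[str, str] | pd.Series,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    epsilon: float = 1e-6,
    seed: int | None = 0,
) -> pd.Series:
    """Bootstrapped LDA effect size per feature (log10 scale).

    ``matrix`` is samples x features on the per-million scale; ``classes``
    maps sample -> class label.  Every class needs at least two samples so
    each bootstrap subsample (a ``boot_fraction`` of the class, at least 2)
    supports a covariance estimate.  For more than two classes the score is
    the maximum over class pairs.
    """
    classes = pd.Series(classes).reindex(matrix.index)
    if classes.isna().any():
        raise ValueError("classes missing for some samples")
    labels = sorted(classes.unique())
    if len(labels) < 2:
        raise ValueError("need at least two classes")
    idx_by_class = {g: np.flatnonzero((classes == g).to_numpy()) for g in labels}
    too_small = [g for g, idx in idx_by_class.items() if idx.size < 2]
    if too_small:
        raise ValueError(f"classes with < 2 samples: {too_small}")

    x = matrix.to_numpy(dtype=float)
    p = x.shape[1]
    rng = np.random.default_rng(seed)
    effects = np.zeros((n_boot, p))
    for b in range(n_boot):
        sub = {
            g: rng.choice(idx, size=max(2, round(boot_fraction * idx.size)), replace=False)
            for g, idx in idx_by_class.items()
        }
        pair_effect = np.zeros(p)
        for ga, gb in itertools.combinations(labels, 2):
            xa, xb = x[sub[ga]], x[sub[gb]]
            dmu = xa.mean(axis=0) - xb.mean(axis=0)
            sw = (np.cov(xa, rowvar=False) * (len(xa) - 1)
                  + np.cov(xb, rowvar=False) * (len(xb) - 1)) / (len(xa) + len(xb) - 2)
            sw = np.atleast_2d(sw) + epsilon * np.eye(p)
            w = np.linalg.solve(sw, dmu)
            wmax = np.abs(w).max()
            if wmax > 0:
                w = w / wmax
            # a feature's discriminant effect is its own contribution to the
            # projected class separation, |w_f * dmu_f| (bounded by |dmu_f|
            # since |w_f| <= 1), averaged with its raw mean difference
            pair_effect = np.maximum(pair_effect, (np.abs(w * dmu) + np.abs(dmu)) / 2.0)
        effects[b] = pair_effect
    mean_effect = effects.mean(axis=0)
    return pd.Series(np.log10(np.maximum(mean_effect, 1.0)), index=matrix.columns)


@dataclass(frozen=True)
class LefseResult:
    feature_id: str
    kw_p: float
    lda_score: float
    enriched_class: str
    passes: bool


def run_lefse(
    table: OtuTable | pd.DataFrame,
    classes: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    lda_threshold: float = 4.0,
    n_boot: int = 30,
    boot_fraction: float = 2.0 / 3.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Screen features by Kruskal-Wallis, score survivors by LDA effect size.

    Accepts an OtuTable (counts) or a samples x features abundance frame.
    Returns one row per feature: ``kw_p``, ``lda_score`` (NaN for features
    failing the screen), ``enriched_class`` (class with the highest mean
    per-million abundance) and ``passes`` (kw_p < alpha and
    lda_score >= lda_threshold), sorted by descending score.
    """
    if isinstance(table, OtuTable):
        matrix = table.counts.T
    else:
        matrix = table
    classes = pd.Series(classes).reindex(matrix.index)
    if classes.nunique() < 2:
        raise ValueError("need at least two classes")
    ppm = to_per_million(matrix)

    labels = classes.to_numpy()
    kw_p = {}
    for feature in ppm.columns:
        _, p = kruskal_wallis(ppm[feature].to_numpy(), labels)
        kw_p[feature] = p
    survivors = [f for f in ppm.columns if kw_p[f] < alpha]
    scores = (
        lda_effect_size(ppm[survivors], classes, n_boot=n_boot,
                        boot_fraction=boot_fraction, seed=seed)
        if survivors
        else pd.Series(dtype=float)
    )
    class_means = ppm.groupby(classes).mean()
    rows = []
    for feature in ppm.columns:
        score = float(scores[feature]) if feature in scores.index else float("nan")
        passes = feature in scores.index and kw_p[feature] < alpha and score >= lda_threshold
        rows.append(
            LefseResult(
                feature_id=feature,
                kw_p=kw_p[feature],
                lda_score=score,
                enriched_class=str(class_means[feature].idxmax()),
                passes=passes,
            )
        )
    out = pd.DataFrame([r.__dict__ for r in rows]).set_index("feature_id")
    return out.sort_values("lda_score", ascending=False, na_position="last")
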