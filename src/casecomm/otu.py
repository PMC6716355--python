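"""De novo OTU clustering at 97% identity and seeded rarefaction.

Clustering is greedy abundance-sorted centroid clustering (uclust-style
semantics): sequences are visited in decreasing total-count order and join
the first centroid they match at or above the identity threshold, otherwise
found a new OTU.  Identity comes from a global Needleman-Wunsch alignment
(match +1, mismatch -1, gap -2) as matches over alignment columns, terminal
gap columns excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from Bio import Align

from .tables import OtuTable, UniqueSeqTable


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two sequences.

    Identity = matching columns / alignment columns, excluding terminal-gap
    columns (overhangs do not count against identity).  Symmetric.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _ALIGNER.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    start, end = 0, len(s1)
    while start < end and (s1[start] == "-" or s2[start] == "-"):
        start += 1
    while end > start and (s1[end - 1] == "-" or s2[end - 1] == "-"):
        end -= 1
    if end == start:
        return 0.0
    matches = sum(1 for i in range(start, end) if s1[i] == s2[i])
    return matches / (end - start)


def greedy_cluster(table: UniqueSeqTable, threshold: float = 0.97) -> OtuTable:
    """Cluster unique sequences into OTUs at ``threshold`` identity.

    Deterministic: input rows are first put in canonical order (decreasing
    total count, ties by sequence string), so the result is invariant to the
    table's row order.  Each sequence joins the first existing centroid with
    identity >= threshold, else founds a new OTU with itself as
    representative.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    totals = table.counts.sum(axis=1)
    order = sorted(table.counts.index, key=lambda i: (-totals[i], table.sequences[i]))

    centroids: list[str] = []  # otu ids in founding order
    reps: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    assignment: dict[str, str] = {}
    for seq_id in order:
        seq = table.sequences[seq_id]
        home = None
        for otu_id in centroids:
            if pairwise_identity(seq, reps[otu_id]) >= threshold:
                home = otu_id
                break
        if home is None:
            home = f"OTU{len(centroids) + 1}"
            centroids.append(home)
            reps[home] = seq
        members.setdefault(home, []).append(seq_id)
        assignment[seq_id] = home

    counts = pd.DataFrame(
        np.zeros((len(centroids), table.counts.shape[1]), dtype=np.int64),
        index=centroids,
        columns=table.counts.columns,
    )
    for seq_id, otu_id in assignment.items():
        counts.loc[otu_id] += table.counts.loc[seq_id].to_numpy()
    return OtuTable(
        counts=counts,
        representatives=reps,
        members={o: tuple(m) for o, m in members.items()},
    )


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    Reproducible: the multivariate hypergeometric draw per sample comes from
    a single seeded generator, consumed in column order.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    sizes = table.library_sizes
    kept, dropped = [], []
    data = {}
    for sample in table.sample_ids:
        total = int(sizes[sample])
        if total < depth:
            dropped.append(sample)
            continue
        col = table.counts[sample].to_numpy()
        data[sample] = rng.multivariate_hypergeometric(col, depth)
        kept.append(sample)
    if dropped:
        warnings.warn(
            f"rarefy: dropped {len(dropped)} samples below depth {depth}: "
            f"{dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    counts = pd.DataFrame(data, index=table.counts.index, columns=kept, dtype=np.int64)
    return OtuTable(
        counts=counts,
        representatives=dict(table.representatives),
        members=dict(table.members),
    )
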