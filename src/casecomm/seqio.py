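"""Paired-read processing: demultiplex, merge, quality filter, dereplicate.

Mirrors a mothur-style amplicon intake: read pairs are assigned to samples by
exact 6-bp barcode + primer match, assembled into one scaffold requiring a
minimum 10-bp overlap, filtered on length / mean quality / ambiguous bases,
and collapsed to unique full-length sequences per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .tables import UniqueSeqTable

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PairedRead:
    read_id: str
    seq1: str
    qual1: np.ndarray  # phred scores
    seq2: str
    qual2: np.ndarray

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


def _decode_qual(q: str) -> np.ndarray:
    return np.frombuffer(q.encode(), dtype=np.uint8).astype(np.int64) - 33


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[PairedRead]:
    """Stream mate pairs from two phred+33 FASTQ files (same order)."""
    with open(r1_path) as f1, open(r2_path) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            rid = t1.split()[0].removesuffix("/1")
            yield PairedRead(rid, s1.upper(), _decode_qual(q1), s2.upper(), _decode_qual(q2))


@dataclass(frozen=True)
class MergedRead:
    read_id: str
    seq: str
    qual: np.ndarray


def merge_pair(
    read: PairedRead, min_overlap: int = 10, min_identity: float = 0.9
) -> MergedRead | None:
    """Assemble a mate pair into one scaffold, or return None (rejection).

    Candidate overlaps align the 3' end of mate 1 against the reverse
    complement of mate 2.  Among overlaps of at least ``min_overlap`` bases
    whose identity reaches ``min_identity``, the one with the most matching
    positions wins (ties -> longer overlap).  At mismatching overlap columns
    the base with the higher quality is kept (mate 1 on quality ties); the
    merged quality of an overlap column is the max of the two mates.
    """
    if not read.seq1 or not read.seq2:
        raise ValueError("empty mate sequence")
    a1 = np.frombuffer(read.seq1.encode(), dtype=np.uint8)
    rc2_str = revcomp(read.seq2)
    a2 = np.frombuffer(rc2_str.encode(), dtype=np.uint8)
    q2 = read.qual2[::-1]

    best: tuple[int, int] | None = None  # (matches, overlap)
    max_o = min(len(a1), len(a2))
    for o in range(min_overlap, max_o + 1):
        m = int((a1[-o:] == a2[:o]).sum())
        if m / o >= min_identity and (best is None or (m, o) > best):
            best = (m, o)
    if best is None:
        return None
    _, o = best

    left_s, left_q = read.seq1[:-o] if o < len(a1) else "", read.qual1[: len(a1) - o]
    ov1, ov2 = a1[-o:], a2[:o]
    q_ov1, q_ov2 = read.qual1[-o:], q2[:o]
    take1 = (ov1 == ov2) | (q_ov1 >= q_ov2)
    ov = np.where(take1, ov1, ov2)
    ov_q = np.maximum(q_ov1, q_ov2)
    seq = left_s + ov.tobytes().decode() + rc2_str[o:]
    qual = np.concatenate([left_q, ov_q, q2[o:]])
    return MergedRead(read.read_id, seq, qual)


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reason: str | None = None


def qc_filter(
    seq: str, qual: np.ndarray, min_length: int = 200, min_mean_quality: float = 30.0
) -> QcResult:
    """Length / mean-quality / ambiguity filter for a merged read.

    A read fails if it is shorter than ``min_length``, its mean phred score
    is <= ``min_mean_quality`` (the removal rule is "average quality score
    <= 30", applied verbatim), or it contains any N.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    if len(seq) < min_length:
        return QcResult(False, "length")
    if float(np.mean(qual)) <= min_mean_quality:
        return QcResult(False, "quality")
    if "N" in seq:
        return QcResult(False, "ambiguous")
    return QcResult(True)


def demultiplex(
    reads: Iterable[PairedRead],
    barcode_map: Mapping[str, str],
    fwd_primer: str,
    rev_primer: str,
) -> tuple[dict[str, list[PairedRead]], list[tuple[str, str]]]:
    """Assign read pairs to samples by exact barcode + primer prefixes.

    A pair is assigned iff mate 1 starts with ``barcode + fwd_primer`` for
    some sample (the forward mate is canonical) and mate 2 starts with the
    same sample's ``barcode + rev_primer``; prefixes are trimmed from
    retained reads.  Everything else goes to the discard log as
    ``(read_id, reason)``.
    """
    for sample, bc in barcode_map.items():
        if len(bc) != 6:
            raise ValueError(f"barcode for {sample!r} has length {len(bc)} != 6")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate barcodes in barcode map")
    by_barcode = {bc: sample for sample, bc in barcode_map.items()}

    assigned: dict[str, list[PairedRead]] = {s: [] for s in barcode_map}
    discarded: list[tuple[str, str]] = []
    n_fwd = len(fwd_primer)
    n_rev = len(rev_primer)
    for read in reads:
        bc = read.seq1[:6]
        sample = by_barcode.get(bc)
        if sample is None:
            discarded.append((read.read_id, "barcode"))
            continue
        if read.seq1[6 : 6 + n_fwd] != fwd_primer:
            discarded.append((read.read_id, "fwd_primer"))
            continue
        if read.seq2[:6] != bc or read.seq2[6 : 6 + n_rev] != rev_primer:
            discarded.append((read.read_id, "rev_primer"))
            continue
        assigned[sample].append(
            PairedRead(
                read.read_id,
                read.seq1[6 + n_fwd :],
                read.qual1[6 + n_fwd :],
                read.seq2[6 + n_rev :],
                read.qual2[6 + n_rev :],
            )
        )
    return assigned, discarded


def dereplicate(
    per_sample_seqs: Mapping[str, Sequence[str]], control_ids: Iterable[str] = ()
) -> UniqueSeqTable:
    """Collapse identical full-length strings into a unique-sequence table.

    Row order is canonical: decreasing total count, ties broken by sequence
    string, so the table is invariant to input read order.
    """
    import pandas as pd

    samples = list(per_sample_seqs)
    tally: dict[str, dict[str, int]] = {}
    for sample in samples:
        for seq in per_sample_seqs[sample]:
            tally.setdefault(seq, {}).setdefault(sample, 0)
            tally[seq][sample] += 1
    totals = {seq: sum(c.values()) for seq, c in tally.items()}
    ordered = sorted(tally, key=lambda s: (-totals[s], s))
    ids = [f"U{i + 1:06d}" for i in range(len(ordered))]
    counts = pd.DataFrame(
        [[tally[seq].get(s, 0) for s in samples] for seq in ordered],
        index=ids,
        columns=samples,
        dtype=np.int64,
    )
    return UniqueSeqTable(
        counts=counts,
        sequences=dict(zip(ids, ordered)),
        control_ids=frozenset(control_ids) & set(samples),
    )


@dataclass
class ReadAccounting:
    """Per-stage read conservation: input = retained + discarded."""

    input_pairs: int = 0
    demux_assigned: int = 0
    demux_discarded: int = 0
    merge_ok: int = 0
    merge_rejected: int = 0
    qc_passed: int = 0
    qc_failed: int = 0

    def check(self) -> None:
        assert self.input_pairs == self.demux_assigned + self.demux_discarded
        assert self.demux_assigned == self.merge_ok + self.merge_rejected
        assert self.merge_ok == self.qc_passed + self.qc_failed


def process_fastq(
    r1_path: str | Path,
    r2_path: str | Path,
    barcode_map: Mapping[str, str],
    fwd_primer: str,
    rev_primer: str,
    control_ids: Iterable[str] = (),
    min_overlap: int = 10,
    min_length: int = 200,
    min_mean_quality: float = 30.0,
) -> tuple[UniqueSeqTable, ReadAccounting, list[tuple[str, str]]]:
    """Full intake: demultiplex -> merge -> QC -> dereplicate."""
    acct = ReadAccounting()
    reads = list(read_fastq_pairs(r1_path, r2_path))
    acct.input_pairs = len(reads)
    assigned, discarded = demultiplex(reads, barcode_map, fwd_primer, rev_primer)
    acct.demux_assigned = sum(len(v) for v in assigned.values())
    acct.demux_discarded = len(discarded)
    log = list(discarded)
    per_sample: dict[str, list[str]] = {s: [] for s in assigned}
    for sample, pairs in assigned.items():
        for pair in pairs:
            merged = merge_pair(pair, min_overlap=min_overlap)
            if merged is None:
                acct.merge_rejected += 1
                log.append((pair.read_id, "merge"))
                continue
            acct.merge_ok += 1
            qc = qc_filter(merged.seq, merged.qual, min_length, min_mean_quality)
            if qc.passed:
                acct.qc_passed += 1
                per_sample[sample].append(merged.seq)
            else:
                acct.qc_failed += 1
                log.append((pair.read_id, f"qc:{qc.reason}"))
    acct.check()
    empty = [s for s, seqs in per_sample.items() if not seqs]
    if empty:
        warnings.warn(f"{len(empty)} samples with no surviving reads")
    return dereplicate(per_sample, control_ids=control_ids), acct, log
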