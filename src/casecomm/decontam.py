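"""Iterative negative-control decontamination of a unique-sequence table.

The procedure removes suspected reagent/laboratory contaminant genotypes and
noise using sterile negative-control libraries, in four steps:

1. a unique sequence is kept only if some *experimental* library carries it at
   a relative abundance at least ``control_ratio`` (default 10) times its
   maximum relative abundance across the negative controls;
2. a unique sequence is kept only if it accounts for at least
   ``min_relabund`` (default 0.1%) of at least one experimental library;
3. a sample is discarded when filtering has removed more than
   ``max_filtered_fraction`` (default 75%) of its starting reads, i.e. it
   retains less than 25% — such libraries are deemed too contaminated;
4. steps 1-3 are repeated, with relative abundances recomputed from the
   reduced table, until a full pass removes nothing (a fixed point).

Relative abundances always use the *current* (post-removal) library sizes;
step 3 compares against the original starting sizes.  Negative controls never
count as experimental libraries in steps 1-2 but are themselves subject to
the step-3 discard (in practice they lose essentially all their reads in
step 1 and drop out).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from .tables import UniqueSeqTable


@dataclass(frozen=True)
class DecontamParams:
    control_ratio: float = 10.0
    min_relabund: float = 0.001
    max_filtered_fraction: float = 0.75
    #: step 2 abundances use post-step-1 (current) library sizes when True
    step2_on_current: bool = True

    def __post_init__(self) -> None:
        if self.control_ratio <= 0:
            raise ValueError("control_ratio must be positive")
        if not 0.0 < self.min_relabund < 1.0:
            raise ValueError("min_relabund must be in (0, 1)")
        if not 0.0 < self.max_filtered_fraction < 1.0:
            raise ValueError("max_filtered_fraction must be in (0, 1)")


@dataclass
class IterationRecord:
    iteration: int
    removed_sequences_step1: list[str]
    removed_sequences_step2: list[str]
    removed_samples: list[str]
    reads_before: int
    reads_after: int


@dataclass
class DecontamReport:
    """Per-iteration ledger of what the procedure removed and kept."""

    iterations: list[IterationRecord] = field(default_factory=list)
    final_retained_samples: list[str] = field(default_factory=list)
    per_sample_retained_fraction: dict[str, float] = field(default_factory=dict)
    starting_sizes: dict[str, int] = field(default_factory=dict)
    all_experimental_discarded: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    @property
    def total_reads_before(self) -> int:
        return self.iterations[0].reads_before if self.iterations else 0

    @property
    def total_reads_after(self) -> int:
        return self.iterations[-1].reads_after if self.iterations else 0

    def retained_read_percent(self) -> float:
        """Reads surviving the whole procedure, as % of the starting total."""
        if self.total_reads_before == 0:
            return 0.0
        return 100.0 * self.total_reads_after / self.total_reads_before

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "iterations": [asdict(it) for it in self.iterations],
            "final_retained_samples": self.final_retained_samples,
            "per_sample_retained_fraction": self.per_sample_retained_fraction,
            "starting_sizes": self.starting_sizes,
            "all_experimental_discarded": self.all_experimental_discarded,
            "retained_read_percent": self.retained_read_percent(),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def read_accounting_percent(reads_retained: int, reads_total: int) -> float:
    """Retained reads as a percentage of the total, to two decimals."""
    if reads_total <= 0:
        raise ValueError("reads_total must be positive")
    return round(100.0 * reads_retained / reads_total, 2)


def relative_abundance(table: UniqueSeqTable) -> pd.DataFrame:
    """Per-sample fractions against the sample's current library size."""
    sizes = table.library_sizes
    if (sizes == 0).any():
        empty = list(sizes.index[sizes == 0])
        raise ValueError(f"zero-size libraries: {empty}")
    return table.counts / sizes


def step1_control_ratio(table: UniqueSeqTable, params: DecontamParams) -> set[str]:
    """Keep sequences that beat their control background by ``control_ratio``.

    A sequence is kept iff some experimental library carries it at
    >= ``control_ratio`` times its maximum relative abundance in any negative
    control.  Sequences absent from every control are kept iff present in any
    experimental library.  With no control samples left in the table, every
    sequence present in an experimental library is kept.
    """
    exp = table.experimental_ids
    if not exp:
        raise ValueError("no experimental samples in table")
    rel = relative_abundance(table)
    ctrl = sorted(table.control_ids)
    max_ctrl = rel[ctrl].max(axis=1) if ctrl else pd.Series(0.0, index=rel.index)
    max_exp = rel[exp].max(axis=1)
    kept = (max_exp >= params.control_ratio * max_ctrl) & (max_exp > 0)
    return set(kept.index[kept])


def step2_min_abundance(table: UniqueSeqTable, params: DecontamParams) -> set[str]:
    """Keep sequences reaching ``min_relabund`` in at least one experimental library."""
    if table.counts.empty:
        return set()
    exp = table.experimental_ids
    if not exp:
        return set()
    rel = relative_abundance(table)
    kept = rel[exp].max(axis=1) >= params.min_relabund
    return set(kept.index[kept])


def step3_sample_retention(
    table: UniqueSeqTable, starting_sizes: Mapping[str, int], params: DecontamParams
) -> set[str]:
    """Keep samples that retain at least ``1 - max_filtered_fraction`` of their
    starting reads; exactly the boundary fraction is kept (only strictly
    "over 75%" filtered samples are discarded)."""
    current = table.library_sizes
    kept = set()
    for sample in table.sample_ids:
        if sample not in starting_sizes:
            raise KeyError(f"sample {sample!r} missing from starting_sizes")
        start = starting_sizes[sample]
        if start <= 0:
            continue
        if current[sample] / start >= 1.0 - params.max_filtered_fraction:
            kept.add(sample)
    return kept


def run_decontam(
    table: UniqueSeqTable, params: DecontamParams | None = None
) -> tuple[UniqueSeqTable, DecontamReport]:
    """Apply steps 1-3 repeatedly until a fixed point.

    Each iteration applies step 1, re-derives abundances on the reduced
    table, applies step 2, then step 3 against the original starting sizes.
    Samples discarded by step 3 (controls included) no longer contribute to
    any relative-abundance maximum.  Terminates in at most
    (#sequences + #samples) iterations since every non-final pass removes
    something.  If every experimental sample is discarded the report flags it
    and the (empty) table is returned.  A table without negative controls is
    accepted with a warning (step 1 then only requires presence in an
    experimental library); this keeps the procedure idempotent, since its
    own output normally has every control discarded.
    """
    params = params or DecontamParams()
    if not table.control_ids:
        warnings.warn(
            "no negative controls in table: step 1 reduces to a presence filter "
            "(this is the expected state when re-running on decontaminated output)"
        )
    starting_sizes = {s: int(n) for s, n in table.library_sizes.items()}
    report = DecontamReport(starting_sizes=starting_sizes)

    current = table
    iteration = 0
    while True:
        iteration += 1
        reads_before = int(current.counts.to_numpy().sum())

        kept1 = step1_control_ratio(current, params)
        removed1 = sorted(set(current.counts.index) - kept1)
        after1 = current.subset(seq_ids=kept1)

        # step 2: denominator is the post-step-1 (current) library size by
        # default, or the iteration-start size when step2_on_current is False;
        # samples emptied by step 1 cannot support a qualifying abundance
        sizes2 = after1.library_sizes if params.step2_on_current else current.library_sizes
        exp_nz = [s for s in after1.experimental_ids if sizes2[s] > 0]
        if after1.counts.empty or not exp_nz:
            kept2: set[str] = set()
        else:
            rel2 = after1.counts[exp_nz] / sizes2[exp_nz]
            mask2 = rel2.max(axis=1) >= params.min_relabund
            kept2 = set(mask2.index[mask2])
        removed2 = sorted(set(after1.counts.index) - kept2)
        after2 = after1.subset(seq_ids=kept2)

        kept_samples = step3_sample_retention(after2, starting_sizes, params)
        removed_samples = sorted(set(after2.sample_ids) - kept_samples)
        after3 = after2.subset(sample_ids=kept_samples)

        reads_after = int(after3.counts.to_numpy().sum())
        report.iterations.append(
            IterationRecord(
                iteration=iteration,
                removed_sequences_step1=removed1,
                removed_sequences_step2=removed2,
                removed_samples=removed_samples,
                reads_before=reads_before,
                reads_after=reads_after,
            )
        )
        changed = bool(removed1 or removed2 or removed_samples)
        current = after3
        if not current.experimental_ids:
            report.all_experimental_discarded = True
            break
        if not changed:
            break

    report.final_retained_samples = list(current.sample_ids)
    report.per_sample_retained_fraction = {
        s: float(current.library_sizes[s]) / starting_sizes[s]
        for s in current.sample_ids
        if starting_sizes[s] > 0
    }
    return current, report
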