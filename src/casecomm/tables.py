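"""Core in-memory containers and their plain-text serialisations.

The pipeline moves data through two matrix containers: a
:class:`UniqueSeqTable` holding dereplicated full-length sequences (the unit
the decontamination procedure filters) and an :class:`OtuTable` produced by
clustering.  Both store counts as a pandas DataFrame with *rows = features,
columns = samples*; sample annotation travels separately as a metadata frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STAGES = ("I", "II", "III", "V", "VI", "VII")
COMPARTMENTS = ("casing_soil", "upper_substrate", "lower_substrate", "fruit_body")
TREATMENTS = ("normal", "no_casing", "sterilized")

META_COLUMNS = ["sample_id", "stage", "compartment", "treatment", "is_negative_control"]


@dataclass(frozen=True)
class SampleMeta:
    """Annotation for one library in the cultivation design."""

    sample_id: str
    stage: str
    compartment: str
    treatment: str
    is_negative_control: bool = False

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")


def design_to_frame(design: Iterable[SampleMeta]) -> pd.DataFrame:
    rows = [
        (m.sample_id, m.stage, m.compartment, m.treatment, m.is_negative_control)
        for m in design
    ]
    return pd.DataFrame(rows, columns=META_COLUMNS).set_index("sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    meta["is_negative_control"] = meta["is_negative_control"].astype(bool)
    return meta


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


@dataclass
class UniqueSeqTable:
    """Sample x unique-sequence count matrix.

    ``counts``: DataFrame, rows indexed by sequence id, columns by sample id,
    non-negative integers.  ``sequences`` maps sequence id to its DNA string;
    strings are unique across rows.  ``control_ids`` marks the negative-control
    libraries.
    """

    counts: pd.DataFrame
    sequences: dict[str, str]
    control_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.control_ids = frozenset(self.control_ids)
        if not set(self.counts.index) <= set(self.sequences):
            missing = set(self.counts.index) - set(self.sequences)
            raise ValueError(f"rows without a sequence string: {sorted(missing)[:5]}")
        seqs = [self.sequences[i] for i in self.counts.index]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate sequence strings among rows")
        unknown = self.control_ids - set(self.counts.columns)
        if unknown:
            raise ValueError(f"control ids not among samples: {sorted(unknown)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def experimental_ids(self) -> list[str]:
        return [s for s in self.counts.columns if s not in self.control_ids]

    def subset(self, seq_ids=None, sample_ids=None) -> "UniqueSeqTable":
        counts = self.counts
        if seq_ids is not None:
            counts = counts.loc[[i for i in counts.index if i in set(seq_ids)]]
        if sample_ids is not None:
            keep = set(sample_ids)
            counts = counts[[s for s in counts.columns if s in keep]]
        return UniqueSeqTable(
            counts=counts.copy(),
            sequences={i: self.sequences[i] for i in counts.index},
            control_ids=self.control_ids & set(counts.columns),
        )

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "sequence", [self.sequences[i] for i in out.index])
        out.index.name = "sequence_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(
        cls, path: str | Path, control_ids: Iterable[str] = ()
    ) -> "UniqueSeqTable":
        df = pd.read_csv(path, sep="\t", index_col="sequence_id")
        sequences = df["sequence"].to_dict()
        counts = df.drop(columns="sequence").astype(np.int64)
        return cls(counts=counts, sequences=sequences, control_ids=frozenset(control_ids))


@dataclass
class OtuTable:
    """Sample x OTU count matrix with representative sequences.

    Every input sequence belongs to exactly one OTU, so per-sample OTU counts
    sum to the sample's input read total.
    """

    counts: pd.DataFrame  # rows = OTU ids, columns = sample ids
    representatives: dict[str, str]  # otu_id -> representative DNA string
    members: dict[str, tuple[str, ...]]  # otu_id -> member sequence ids

    def __post_init__(self) -> None:
        if set(self.counts.index) != set(self.representatives):
            raise ValueError("representatives must cover exactly the OTU rows")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        sizes = self.library_sizes
        if (sizes == 0).any():
            empty = list(sizes.index[sizes == 0])
            raise ValueError(f"zero-total samples: {empty}")
        return self.counts / sizes

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "representative", [self.representatives[i] for i in out.index])
        out.insert(1, "members", [",".join(self.members[i]) for i in out.index])
        out.index.name = "otu_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col="otu_id")
        reps = df["representative"].to_dict()
        members = {
            i: tuple(str(m).split(",")) if pd.notna(m) and str(m) else ()
            for i, m in df["members"].items()
        }
        counts = df.drop(columns=["representative", "members"]).astype(np.int64)
        return cls(counts=counts, representatives=reps, members=members)


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
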