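"""Shared fixtures: the simulated study and its downstream products.

Expensive chain (simulate -> decontaminate -> cluster -> rarefy) is built
once per session and shared read-only across test modules.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from casecomm import (
    DecontamParams,
    enumerate_design,
    greedy_cluster,
    make_stage_profiles,
    rarefy,
    run_decontam,
    simulate_counts,
)
from casecomm.tables import UniqueSeqTable


@pytest.fixture(scope="session")
def design():
    return enumerate_design()


@pytest.fixture(scope="session")
def profiles():
    return make_stage_profiles(50, seed=1)


@pytest.fixture(scope="session")
def sim(design, profiles):
    """Full-design simulation at default conditions, seed 7."""
    table, truth = simulate_counts(design, profiles, seed=7)
    return table, truth


@pytest.fixture(scope="session")
def decontaminated(sim):
    table, _ = sim
    return run_decontam(table, DecontamParams())


@pytest.fixture(scope="session")
def otu_table(decontaminated):
    filtered, _ = decontaminated
    return greedy_cluster(filtered, threshold=0.97)


@pytest.fixture(scope="session")
def rarefied(otu_table):
    return rarefy(otu_table, 7096, seed=11)


@pytest.fixture(scope="session")
def meta_by_sample(design):
    return {m.sample_id: m for m in design}


def make_table(counts: dict[str, dict[str, int]], controls=()) -> UniqueSeqTable:
    """Build a UniqueSeqTable from {sample: {seq_id: count}} with dummy
    distinct sequence strings."""
    samples = list(counts)
    seq_ids = sorted({u for col in counts.values() for u in col})
    mat = pd.DataFrame(
        [[counts[s].get(u, 0) for s in samples] for u in seq_ids],
        index=seq_ids,
        columns=samples,
        dtype=np.int64,
    )
    # distinct dummy sequences: index encoded in base-4 over ACGT
    def seq_for(i: int) -> str:
        digits = np.base_repr(i, base=4).zfill(8)
        return "".join("ACGT"[int(c)] for c in digits)

    return UniqueSeqTable(
        counts=mat,
        sequences={u: seq_for(i) for i, u in enumerate(seq_ids)},
        control_ids=frozenset(controls),
    )
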