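"""Synthetic study generator: design, stage profiles, contaminated libraries, FASTQ.

Emulates a casing-soil cultivation experiment: 150 libraries across six
cultivation stages, three casing treatments and up to four compartments, with
stage-structured genus-level community profiles, a shared reagent-style
contaminant background that dominates the sterile stage-II negative controls,
and sample-private sub-0.1% noise sequences.  Every simulated sequence carries
a ground-truth origin label (genuine / contaminant / noise) so downstream
filtering can be scored exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import SampleMeta, UniqueSeqTable

# Literal 16S V3-V4 primer pair used by the read writer and demultiplexer
# (a fixed non-degenerate realisation; matching is exact).
FWD_PRIMER = "ACTCCTACGGGAGGCAGCAG"  # 338F
REV_PRIMER = "GGACTACCAGGGTATCTAAT"  # 806R

AMPLICON_LEN = 250
READ_LEN = 150

#: Dominant-taxon (Burkholderia-like) expected fraction in casing soil per
#: stage: low in the original soil, peaking once hyphae colonise the casing,
#: dipping at primordium formation and partially rebounding at fruiting.
DOMINANT_CASING_TRAJECTORY = {"I": 0.1195, "V": 0.5579, "VI": 0.3514, "VII": 0.4560}
#: In substrate compartments the dominant taxon sits at a moderate level.
DOMINANT_OTHER = 0.30


@dataclass(frozen=True)
class TruthLabels:
    """Ground-truth origin of every simulated sequence."""

    origin: dict[str, str]  # sequence_id -> genuine | contaminant | noise

    def __post_init__(self) -> None:
        bad = {v for v in self.origin.values()} - {"genuine", "contaminant", "noise"}
        if bad:
            raise ValueError(f"unknown origin labels: {bad}")

    def ids_with_origin(self, origin: str) -> set[str]:
        return {k for k, v in self.origin.items() if v == origin}


@dataclass
class StageProfileSet:
    """Expected relative-abundance profiles per (stage, compartment)."""

    taxa: list[str]
    profiles: dict[tuple[str, str], np.ndarray]

    def profile(self, stage: str, compartment: str) -> np.ndarray:
        return self.profiles[(stage, compartment)]

    def as_mapping(self, stage: str, compartment: str) -> dict[str, float]:
        return dict(zip(self.taxa, self.profiles[(stage, compartment)]))


def enumerate_design() -> list[SampleMeta]:
    """Enumerate the full 150-sample cultivation design.

    Normal casing treatment (90 libraries): stage I casing soil only; stages
    II-III upper and lower substrate; stages V-VI casing + upper + lower;
    stage VII adds fruit bodies.  The no-casing (24) and sterilized-casing
    (36) treatments repeat the stage V-VI strategy without / with a casing
    layer.  Six replicates everywhere.  Stage II normal-treatment libraries
    (sterilized substrate before inoculation) are the negative controls.
    """
    plan: list[tuple[str, str, str]] = []
    for stage in ("I",):
        plan.append(("normal", stage, "casing_soil"))
    for stage in ("II", "III"):
        plan += [("normal", stage, "upper_substrate"), ("normal", stage, "lower_substrate")]
    for stage in ("V", "VI"):
        plan += [
            ("normal", stage, "casing_soil"),
            ("normal", stage, "upper_substrate"),
            ("normal", stage, "lower_substrate"),
        ]
    plan += [
        ("normal", "VII", c)
        for c in ("casing_soil", "upper_substrate", "lower_substrate", "fruit_body")
    ]
    for stage in ("V", "VI"):
        plan += [("no_casing", stage, "upper_substrate"), ("no_casing", stage, "lower_substrate")]
        plan += [
            ("sterilized", stage, "casing_soil"),
            ("sterilized", stage, "upper_substrate"),
            ("sterilized", stage, "lower_substrate"),
        ]

    short = {"casing_soil": "CS", "upper_substrate": "U", "lower_substrate": "L", "fruit_body": "FB"}
    tshort = {"normal": "N", "no_casing": "NC", "sterilized": "ST"}
    design = []
    for treatment, stage, compartment in plan:
        for rep in range(1, 7):
            design.append(
                SampleMeta(
                    sample_id=f"{tshort[treatment]}.{stage}.{short[compartment]}.{rep}",
                    stage=stage,
                    compartment=compartment,
                    treatment=treatment,
                    is_negative_control=(stage == "II" and treatment == "normal"),
                )
            )
    return design


def make_stage_profiles(
    n_taxa: int = 50, seed: int = 0, concentration: float = 200.0
) -> StageProfileSet:
    """Build per-(stage, compartment) community profiles.

    Taxon 0 ("Burkholderia_like") follows the fixed casing-soil trajectory in
    :data:`DOMINANT_CASING_TRAJECTORY`; the remaining mass is spread over the
    other taxa by a seeded symmetric Dirichlet draw (total concentration
    ``concentration``), drawn independently per profile so stages genuinely
    differ and group tests have signal.
    """
    if n_taxa < 10:
        raise ValueError("n_taxa must be >= 10 to host the named taxa")
    rng = np.random.default_rng(seed)
    taxa = ["Burkholderia_like"] + [f"taxon_{i:03d}" for i in range(1, n_taxa)]
    alpha = np.full(n_taxa - 1, concentration / (n_taxa - 1))
    combos = sorted({(m.stage, m.compartment) for m in enumerate_design()})
    profiles: dict[tuple[str, str], np.ndarray] = {}
    for stage, compartment in combos:
        if compartment == "casing_soil":
            dom = DOMINANT_CASING_TRAJECTORY[stage]
        else:
            dom = DOMINANT_OTHER
        rest = rng.dirichlet(alpha) * (1.0 - dom)
        profiles[(stage, compartment)] = np.concatenate([[dom], rest])
    return StageProfileSet(taxa=taxa, profiles=profiles)


def _random_seq(rng: np.random.Generator, length: int = AMPLICON_LEN) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _divergent_seqs(rng: np.random.Generator, n: int, min_div: float = 0.05) -> list[str]:
    """Random amplicons with guaranteed pairwise divergence >= min_div."""
    seqs: list[str] = []
    arrs: list[np.ndarray] = []
    while len(seqs) < n:
        s = _random_seq(rng)
        a = np.frombuffer(s.encode(), dtype=np.uint8)
        if all((a != b).mean() >= min_div for b in arrs):
            seqs.append(s)
            arrs.append(a)
    return seqs


def simulate_counts(
    design: Sequence[SampleMeta],
    profiles: StageProfileSet,
    n_contaminants: int = 10,
    contamination_fraction: float = 0.02,
    noise_fraction: float = 0.0003,
    n_noise_per_sample: int = 6,
    depth_range: tuple[int, int] = (20000, 40000),
    contamination_sigma: float = 0.3,
    seed: int = 0,
) -> tuple[UniqueSeqTable, TruthLabels]:
    """Draw per-library counts mixing genuine, contaminant and noise sequences.

    Each library's depth is uniform in ``depth_range``.  Experimental
    libraries are a single multinomial over [stage profile x genuine share,
    shared contaminant profile x per-sample contamination load, private noise
    slots]; the contamination load is ``contamination_fraction`` scaled by a
    lognormal factor (sigma=``contamination_sigma``), the reagent model in
    which all libraries see the same contaminant pool at variable amplitude.
    Negative controls draw from the contaminant profile only.  Noise
    sequences are sample-private with expected relative abundance
    ``noise_fraction / n_noise_per_sample`` each (well under 0.1%, so they
    land as singletons or doubletons at the default depths).
    """
    if not 0.0 <= contamination_fraction < 1.0:
        raise ValueError("contamination_fraction must be in [0, 1)")
    if not 0.0 <= noise_fraction < 1.0:
        raise ValueError("noise_fraction must be in [0, 1)")
    if depth_range[0] <= 0 or depth_range[1] < depth_range[0]:
        raise ValueError("depth_range must be a positive, ordered pair")

    rng = np.random.default_rng(seed)
    n_taxa = len(profiles.taxa)
    seqs = _divergent_seqs(rng, n_taxa + n_contaminants)
    genuine_ids = [f"g_{name}" for name in profiles.taxa]
    contam_ids = [f"c_{i:03d}" for i in range(n_contaminants)]
    sequences = dict(zip(genuine_ids + contam_ids, seqs))
    origin = {i: "genuine" for i in genuine_ids}
    origin.update({i: "contaminant" for i in contam_ids})

    contam_profile = rng.dirichlet(np.full(n_contaminants, 5.0))

    columns: dict[str, dict[str, int]] = {}
    for meta in design:
        depth = int(rng.integers(depth_range[0], depth_range[1] + 1))
        col: dict[str, int] = {}
        if meta.is_negative_control:
            draws = rng.multinomial(depth, contam_profile)
            for cid, c in zip(contam_ids, draws):
                if c:
                    col[cid] = int(c)
        else:
            load = contamination_fraction * rng.lognormal(0.0, contamination_sigma)
            load = min(load, 0.5)
            noise_ids = [f"n_{meta.sample_id}_{j}" for j in range(n_noise_per_sample)]
            per_noise = noise_fraction / max(n_noise_per_sample, 1)
            genuine_share = 1.0 - load - noise_fraction
            probs = np.concatenate(
                [
                    profiles.profile(meta.stage, meta.compartment) * genuine_share,
                    contam_profile * load,
                    np.full(n_noise_per_sample, per_noise),
                ]
            )
            draws = rng.multinomial(depth, probs / probs.sum())
            ids = genuine_ids + contam_ids + noise_ids
            for sid, c in zip(ids, draws):
                if c:
                    col[sid] = int(c)
                    if sid.startswith("n_"):
                        sequences.setdefault(sid, _random_seq(rng))
                        origin[sid] = "noise"
        columns[meta.sample_id] = col

    counts = (
        pd.DataFrame(columns)
        .fillna(0)
        .astype(np.int64)
        .reindex(columns=[m.sample_id for m in design])
    )
    # deterministic row order: decreasing total, ties by id
    totals = counts.sum(axis=1)
    order = sorted(counts.index, key=lambda i: (-totals[i], i))
    counts = counts.loc[order]
    table = UniqueSeqTable(
        counts=counts,
        sequences={i: sequences[i] for i in counts.index},
        control_ids=frozenset(m.sample_id for m in design if m.is_negative_control),
    )
    labels = TruthLabels(origin={i: origin[i] for i in counts.index})
    return table, labels


def make_marker_dataset(
    n_per_class: int = 6,
    n_features: int = 50,
    class_labels: Sequence[str] = ("FH", "P", "F", "OS"),
    fold: float = 20.0,
    concentration: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict[str, str]]:
    """Stage-marker benchmark: one planted marker feature per class.

    All features share base weight 1; the marker of class ``c`` has weight
    ``fold`` in that class only.  Per-sample abundances are a Dirichlet draw
    around the class weights (per-feature alpha = weight * concentration), so
    non-marker features have equal weight everywhere and differ between
    classes only through compositional closure.  Returns (samples x features
    relative abundances, sample -> class labels, marker feature -> class).
    """
    rng = np.random.default_rng(seed)
    features = [f"f{i:03d}" for i in range(n_features)]
    planted = {features[i]: c for i, c in enumerate(class_labels)}
    rows, sample_ids, classes = [], [], []
    for ci, c in enumerate(class_labels):
        weights = np.ones(n_features)
        weights[ci] = fold
        for r in range(n_per_class):
            sample_ids.append(f"{c}.{r + 1}")
            classes.append(c)
            rows.append(rng.dirichlet(weights * concentration))
    matrix = pd.DataFrame(rows, index=sample_ids, columns=features)
    return matrix, pd.Series(classes, index=sample_ids), planted


def make_correlated_otu_table(
    n_samples: int = 40,
    block_sizes: Sequence[int] = (5, 5),
    n_anti: int = 1,
    n_independent: int = 9,
    noise_sigma: float = 0.15,
    scale: float = 1000.0,
    seed: int = 0,
) -> tuple[UniqueSeqTable | "OtuTable", dict[str, str]]:
    """OTU table with planted co-occurrence structure for network tests.

    Each block shares a lognormal latent factor (strong positive rank
    correlation within the block); ``n_anti`` OTUs follow the *reciprocal*
    of the first block's factor (negative correlation with it); the rest are
    independent.  Counts are Poisson around ``scale`` x the latent level.
    Returns the table and a role map: otu -> 'block<i>' | 'anti' | 'indep'.
    """
    from .tables import OtuTable

    rng = np.random.default_rng(seed)
    otu_levels: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    factors = [np.exp(rng.normal(0.0, 1.0, n_samples)) for _ in block_sizes]
    i = 0
    for b, size in enumerate(block_sizes):
        for _ in range(size):
            name = f"OTU{i:02d}"
            otu_levels[name] = factors[b] * np.exp(rng.normal(0, noise_sigma, n_samples))
            roles[name] = f"block{b}"
            i += 1
    for _ in range(n_anti):
        name = f"OTU{i:02d}"
        otu_levels[name] = 1.0 / factors[0] * np.exp(rng.normal(0, noise_sigma, n_samples))
        roles[name] = "anti"
        i += 1
    for _ in range(n_independent):
        name = f"OTU{i:02d}"
        otu_levels[name] = np.exp(rng.normal(0.0, 1.0, n_samples))
        roles[name] = "indep"
        i += 1
    counts = pd.DataFrame(
        {f"s{j:02d}": [rng.poisson(scale * otu_levels[o][j]) for o in otu_levels]
         for j in range(n_samples)},
        index=list(otu_levels),
        dtype=np.int64,
    )
    table = OtuTable(
        counts=counts,
        representatives={o: _random_seq(rng) for o in otu_levels},
        members={o: (o,) for o in otu_levels},
    )
    return table, roles


def default_barcode_map(sample_ids: Sequence[str]) -> dict[str, str]:
    """Assign a unique 6-bp barcode to every sample (deterministic)."""
    alphabet = "ACGT"
    codes = ("".join(p) for p in itertools.product(alphabet, repeat=6))
    return {s: next(codes) for s in sample_ids}


def write_fastq_pairs(
    table: UniqueSeqTable,
    barcode_map: Mapping[str, str],
    r1_path: str | Path,
    r2_path: str | Path,
    error_rate: float = 0.0,
    seed: int = 0,
    fwd_primer: str = FWD_PRIMER,
    rev_primer: str = REV_PRIMER,
) -> tuple[Path, Path]:
    """Emit paired FASTQ (phred+33) for every read implied by ``table``.

    R1 = barcode + forward primer + first ``READ_LEN`` bases of the amplicon;
    R2 = barcode + reverse primer + first ``READ_LEN`` bases of the reverse
    complement, so trimmed mates overlap by ``2*READ_LEN - AMPLICON_LEN``
    (50 bp) and merge back to the amplicon.  ``error_rate`` introduces
    uniform substitutions into the amplicon-derived bases.  With
    ``error_rate=0`` the read-processing pipeline reconstructs ``table``
    exactly.
    """
    for sample, bc in barcode_map.items():
        if len(bc) != 6:
            raise ValueError(f"barcode for {sample!r} has length {len(bc)} != 6")
    if len(set(barcode_map.values())) != len(barcode_map):
        raise ValueError("duplicate barcodes in barcode map")
    missing = set(table.sample_ids) - set(barcode_map)
    if missing:
        raise ValueError(f"samples without barcodes: {sorted(missing)[:5]}")

    comp = str.maketrans("ACGTN", "TGCAN")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def mutate(seq: str) -> str:
        if error_rate <= 0:
            return seq
        arr = np.array(list(seq))
        hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
        for i in hits:
            arr[i] = rng.choice(bases[bases != arr[i]])
        return "".join(arr)

    r1_path, r2_path = Path(r1_path), Path(r2_path)
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for sample in table.sample_ids:
            bc = barcode_map[sample]
            col = table.counts[sample]
            for seq_id in table.counts.index[col.to_numpy() > 0]:
                amplicon = table.sequences[seq_id]
                rc = amplicon.translate(comp)[::-1]
                for copy in range(int(col[seq_id])):
                    rid = f"{sample}:{seq_id}:{copy}"
                    s1 = bc + fwd_primer + mutate(amplicon[:READ_LEN])
                    s2 = bc + rev_primer + mutate(rc[:READ_LEN])
                    f1.write(f"@{rid}/1\n{s1}\n+\n{'G' * len(s1)}\n")
                    f2.write(f"@{rid}/2\n{s2}\n+\n{'G' * len(s2)}\n")
    return r1_path, r2_path
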