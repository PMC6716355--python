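"""End-to-end pipeline orchestration with a YAML config and a run manifest.

Stages: simulate/ingest -> qc -> decontam -> cluster -> rarefy -> diversity
-> ordination (+ ANOSIM) -> lefse -> network.  Every stage's inputs,
parameters, seeds and read accounting land in a machine-readable manifest;
any failure is re-raised as :class:`PipelineError` naming the stage.
Randomness is controlled by a single master seed from which per-stage seeds
are derived deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import run_lefse
from .decontam import DecontamParams, run_decontam
from .diversity import alpha_diversity, compare_groups
from .network import build_network, edges_to_frame, write_sif
from .ordination import anosim, bray_curtis, hellinger, nmds
from .otu import greedy_cluster, rarefy
from .synthetic import enumerate_design, make_stage_profiles, simulate_counts
from .tables import UniqueSeqTable, design_to_frame, read_metadata, write_fasta

STAGE_NAMES = [
    "simulate", "qc", "decontam", "cluster", "rarefy",
    "diversity", "ordination", "lefse", "network",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    # input: 'synthetic' generates the study design; 'tsv' ingests count
    # table + metadata paths
    input_mode: str = "synthetic"
    counts_path: str | None = None
    metadata_path: str | None = None
    # synthetic generator
    n_taxa: int = 50
    n_contaminants: int = 10
    contamination_fraction: float = 0.02
    noise_fraction: float = 0.0003
    depth_range: tuple[int, int] = (20000, 40000)
    # decontamination
    control_ratio: float = 10.0
    min_relabund: float = 0.001
    max_filtered_fraction: float = 0.75
    # clustering / rarefaction
    identity: float = 0.97
    rarefaction_depth: int = 7096
    # statistics
    n_permutations: int = 999
    n_boot: int = 30
    lda_threshold: float = 4.0
    kw_alpha: float = 0.05
    rho_threshold: float = 0.75
    edge_alpha: float = 0.05
    network_top_k: int = 20
    group_by: tuple[str, ...] = ("stage", "compartment")

    def __post_init__(self) -> None:
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity must be in (0, 1]")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        if self.input_mode not in ("synthetic", "tsv"):
            raise ValueError("input_mode must be 'synthetic' or 'tsv'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "depth_range" in data:
            data["depth_range"] = tuple(data["depth_range"])
        if "group_by" in data:
            data["group_by"] = tuple(data["group_by"])
        return cls(**data)


def _stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(np.random.SeedSequence([master, STAGE_NAMES.index(stage)]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write outputs + ``manifest.json`` under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()},
        "stages": [],
    }

    def record(stage: str, **info: Any) -> None:
        manifest["stages"].append({"stage": stage, **info})

    # -- simulate / ingest ------------------------------------------------
    stage = "simulate"
    try:
        if config.input_mode == "synthetic":
            design = enumerate_design()
            profiles = make_stage_profiles(config.n_taxa, seed=_stage_seed(config.seed, stage))
            table, truth = simulate_counts(
                design,
                profiles,
                n_contaminants=config.n_contaminants,
                contamination_fraction=config.contamination_fraction,
                noise_fraction=config.noise_fraction,
                depth_range=config.depth_range,
                seed=_stage_seed(config.seed, stage) + 1,
            )
            meta = design_to_frame(design)
        else:
            if not config.counts_path or not config.metadata_path:
                raise ValueError("tsv mode requires counts_path and metadata_path")
            meta = read_metadata(config.metadata_path)
            controls = meta.index[meta["is_negative_control"]]
            table = UniqueSeqTable.read_tsv(config.counts_path, control_ids=controls)
            truth = None
        meta.to_csv(outdir / "metadata.tsv", sep="\t")
        table.write_tsv(outdir / "unique_seqs.tsv")
        record(stage, n_samples=len(table.sample_ids), n_sequences=len(table.counts),
               total_reads=int(table.counts.to_numpy().sum()),
               seed=_stage_seed(config.seed, stage))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- qc ---------------------------------------------------------------
    # count tables arrive post-merge/post-filter; the qc stage records the
    # pass-through accounting (FASTQ intake uses seqio.process_fastq)
    stage = "qc"
    total = int(table.counts.to_numpy().sum())
    record(stage, input_reads=total, retained=total, discarded=0)

    # -- decontam ---------------------------------------------------------
    stage = "decontam"
    try:
        params = DecontamParams(
            control_ratio=config.control_ratio,
            min_relabund=config.min_relabund,
            max_filtered_fraction=config.max_filtered_fraction,
        )
        filtered, report = run_decontam(table, params)
        filtered.write_tsv(outdir / "decontaminated.tsv")
        report.to_json(outdir / "decontam_report.json")
        record(stage, input_reads=report.total_reads_before,
               retained=report.total_reads_after,
               discarded=report.total_reads_before - report.total_reads_after,
               n_iterations=report.n_iterations,
               retained_samples=len(report.final_retained_samples),
               retained_read_percent=report.retained_read_percent())
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- cluster ----------------------------------------------------------
    stage = "cluster"
    try:
        otus = greedy_cluster(filtered, threshold=config.identity)
        otus.write_tsv(outdir / "otu_table.tsv")
        write_fasta(otus.representatives, outdir / "otu_reps.fasta")
        record(stage, n_otus=len(otus.otu_ids), identity=config.identity,
               input_reads=int(filtered.counts.to_numpy().sum()),
               retained=int(otus.counts.to_numpy().sum()), discarded=0)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- rarefy -----------------------------------------------------------
    stage = "rarefy"
    try:
        sizes = otus.library_sizes
        if (sizes < config.rarefaction_depth).all():
            raise ValueError(
                f"rarefaction depth {config.rarefaction_depth} exceeds every "
                f"library size (max {int(sizes.max())})"
            )
        rare = rarefy(otus, config.rarefaction_depth, seed=_stage_seed(config.seed, stage))
        rare.write_tsv(outdir / "otu_rarefied.tsv")
        record(stage, depth=config.rarefaction_depth,
               input_reads=int(otus.counts.to_numpy().sum()),
               retained=int(rare.counts.to_numpy().sum()),
               discarded=int(otus.counts.to_numpy().sum() - rare.counts.to_numpy().sum()),
               retained_samples=len(rare.sample_ids),
               seed=_stage_seed(config.seed, stage))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    group = meta.loc[rare.sample_ids, list(config.group_by)].astype(str).agg("/".join, axis=1)

    # -- diversity --------------------------------------------------------
    stage = "diversity"
    try:
        alpha = alpha_diversity(rare)
        alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t", float_format="%.10g")
        comparisons = pd.concat(
            [compare_groups(alpha[ix], group, index=ix) for ix in ("shannon", "ace")],
            ignore_index=True,
        )
        comparisons.to_csv(outdir / "alpha_comparisons.tsv", sep="\t", index=False,
                           float_format="%.10g")
        record(stage, n_samples=len(alpha), indices=["shannon", "ace", "observed_otus"])
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- ordination -------------------------------------------------------
    stage = "ordination"
    try:
        hel = hellinger(rare)
        dm = bray_curtis(hel)
        dm.write_tsv(outdir / "bray_curtis.tsv")
        embedding = nmds(dm, seed=_stage_seed(config.seed, stage))
        embedding.coordinates.to_csv(outdir / "nmds_coordinates.tsv", sep="\t",
                                     float_format="%.10g")
        ano = anosim(dm, group, n_perm=config.n_permutations,
                     seed=_stage_seed(config.seed, stage) + 1)
        ano.to_json(outdir / "anosim.json")
        record(stage, stress=embedding.stress, nmds_converged=embedding.converged,
               anosim_R=ano.r, anosim_p=ano.p, n_permutations=config.n_permutations,
               seed=_stage_seed(config.seed, stage))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- lefse ------------------------------------------------------------
    stage = "lefse"
    try:
        lefse = run_lefse(rare, group, alpha=config.kw_alpha,
                          lda_threshold=config.lda_threshold, n_boot=config.n_boot,
                          seed=_stage_seed(config.seed, stage))
        lefse.to_csv(outdir / "lefse.tsv", sep="\t", float_format="%.10g")
        record(stage, n_features=len(lefse), n_passing=int(lefse["passes"].sum()),
               lda_threshold=config.lda_threshold, seed=_stage_seed(config.seed, stage))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    # -- network ----------------------------------------------------------
    stage = "network"
    try:
        edges = build_network(rare, k=config.network_top_k,
                              rho_threshold=config.rho_threshold,
                              alpha=config.edge_alpha)
        edges_to_frame(edges).to_csv(outdir / "network_edges.tsv", sep="\t",
                                     index=False, float_format="%.10g")
        write_sif(edges, outdir / "network.sif")
        record(stage, n_edges=len(edges),
               n_positive=sum(e.sign == "positive" for e in edges),
               n_negative=sum(e.sign == "negative" for e in edges))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
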