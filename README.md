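# casecomm — casing-soil 16S community analysis with negative-control decontamination

`casecomm` is a reusable, tested implementation of an amplicon-community
analysis built around an iterative negative-control decontamination
procedure, of the kind used to profile the bacteria of mushroom casing soil
(the soil layer placed over colonised substrate to trigger fruiting).  In
such experiments many libraries — sterilised substrate above all — amplify
mostly reagent and laboratory contaminant DNA, and naive processing badly
distorts the inferred communities.  The package covers the full path from
paired reads to community statistics:

- **seqio** – demultiplex (exact 6-bp barcode + primer), merge mates
  (minimum 10 bp overlap, quality-aware consensus), filter
  (length ≥ 200 bp, mean quality > 30, no ambiguous bases), dereplicate.
- **decontam** – the core procedure.  With negative controls *C* and
  experimental libraries *E*, and relative abundance `r(u, s)` of unique
  sequence *u* in library *s* (computed on current library sizes), iterate
  to a fixed point:
  1. keep *u* only if `max_{s∈E} r(u,s) ≥ 10 · max_{c∈C} r(u,c)`;
  2. keep *u* only if `max_{s∈E} r(u,s) ≥ 0.1%`;
  3. discard any sample that has lost more than 75% of its starting reads;
  4. repeat steps 1–3 until nothing changes.
- **otu** – greedy abundance-sorted centroid clustering at 97% global
  alignment identity; seeded rarefaction (without replacement) to a common
  depth, e.g. 7,096 reads.
- **diversity** – Shannon (natural log) and ACE indices, Welch *t*
  contrasts with Benjamini–Hochberg correction.
- **ordination** – Hellinger transform, Bray–Curtis dissimilarity, NMDS
  (Kruskal stress-1 with monotone regression, multiple starts), ANOSIM
  permutation tests.
- **biomarkers** – LEfSe-style scan: Kruskal–Wallis screen, then a
  bootstrapped linear-discriminant effect size on the per-million scale
  with the conventional threshold LDA ≥ 4.0.
- **network** – signed Spearman co-occurrence networks over the top-20
  OTUs (|ρ| ≥ 0.75, p < 0.05), with SIF export and per-group edge
  intersection.
- **synthetic** – a first-class generator that emulates the study design:
  150 libraries over six cultivation stages, three casing treatments and
  four compartments; stage-structured profiles whose dominant
  *Burkholderia*-like taxon follows 11.95% → 55.79% → 35.14% → 45.60%
  across casing-soil stages; a shared contaminant pool at ~2% load in
  experimental libraries and ~100% in the sterile stage-II negative
  controls; and sample-private sub-0.1% noise sequences.  Every simulated
  sequence carries a truth label, so decontamination, clustering,
  biomarker and network calls can be scored exactly.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each stage can also be driven from the `casecomm` CLI
(`casecomm simulate | qc | decontam | cluster | rarefy | diversity |
ordinate | anosim | lefse | network | all`).

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_decontaminate.py
```

prints

```
design: 150 libraries ({'normal': 90, 'sterilized': 36, 'no_casing': 24}), 12 negative controls
simulated 705 unique sequences ({'noise': 645, 'genuine': 50, 'contaminant': 10}); library sizes 20025-39394
2 iterations to fixed point; 138/150 samples retained (89.21% of reads)
negative controls discarded: 12/12
contaminant reads removed: 100.00%
noise sequences surviving: 0
```

i.e. the four-step procedure removes every contaminant genotype and noise
sequence, and the twelve contaminant-dominated negative controls are the
only libraries discarded.  Continuing with
`analysis/03_cluster_rarefy.py` … `analysis/07_networks.py`: clustering
returns exactly one OTU per surviving taxon (50), Shannon diversity in
casing soil dips at full hyphal colonisation (stage V, mean 2.36) and
peaks at the primordium stage (stage VI, 3.08) — the evenness ordering of
the underlying profiles — NMDS embeds the casing-soil stages at stress
≈ 0.00 with ANOSIM R = 1.0 (p = 0.001), the planted-marker benchmark is
recovered at 100% recall with 0% false-flag rate, and planted correlation
blocks yield 20/20 positive within-block edges while independent null
tables average 0 edges.

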