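# mitosense

A tested, reusable pipeline for mapping mtDNA-haplotype expression
sensitivity onto nuclear gene architecture:

- **de** — per-gene negative-binomial GLM likelihood-ratio contrasts
  (haplotype ANODEV, species, mitonuclear G×G) with BH-FDR and ranked
  gene-list extraction;
- **cluster** — max-gap physical clustering of a gene list along
  chromosome arms, per-arm Kolmogorov–Smirnov uniformity tests, and a
  randomized-gene-list null;
- **safe** — SAFE-style neighborhood attribute enrichment on an
  interaction network (permutation null, per-node heat), plus degree /
  neighborhood-connectivity metrics and Welch group comparisons;
- **rank** — focal-gene scoring by the mean likelihood ratio of direct
  interactors, with cross-sex top-list intersection and an
  interactor-count sensitivity analysis;
- **enrich** — exact hypergeometric over/under gene-set enrichment with
  a matched permutation null;
- **concord** — hierarchical clustering of expression profiles and
  dendrogram-pair concordance: entanglement, two-sided untangling,
  Goodman–Kruskal gamma with a leaf-shuffle permutation test,
  cophenetic correlation, and a rolling membership-window scan;
- **simulate** — a synthetic-data generator that plants known effects
  (DE fold changes, physical gene clusters, network hotspots, module
  enrichment, developmental expression blocks) so every stage has a
  recoverable truth.

## CLI

```sh
mitosense simulate --config demo.yaml --seed 7 --out out/
mitosense de --counts out/counts.tsv --samples out/samples.tsv --sex F --out de_F.tsv
mitosense cluster --genes out/genome.bed --list genes.txt --max-gap 5 --iters 1000 --seed 1 --out clusters.tsv
mitosense safe --network out/network.tsv --attr de_F.tsv --radius 1 --perms 1000 --seed 1 --out safe.tsv
mitosense rank --network out/network.tsv --de-f de_F.tsv --de-m de_M.tsv --out-prefix focal
mitosense enrich --list genes.txt --sets modules.tsv --universe universe.txt --out enrichment.tsv
mitosense concord --expr-a dev.tsv --expr-b profiles.tsv --out-prefix concord
mitosense all --config demo.yaml --seed 7 --out out/
```

`all` runs every stage under one master seed (per-stage derived seeds)
and writes `manifest.json` recording parameters, seeds, and output-file
hashes; a rerun with the same config is byte-identical. The config is a
YAML/JSON mapping mirroring `mitosense.pipeline.DEFAULT_CONFIG`; unknown
keys are rejected. Exit codes: 0 ok, 1 stage failure, 2 config error.

## Conventions

Coordinates are 0-based half-open internally (BED native; GFF3 shifted
on input); chromosomal linearization uses gene midpoints. Max-gap
clusters are defined on gene ranks (≤ `max_gap` intervening non-members),
not base pairs. Empirical p-values use the +1 correction and so are
never exactly zero. All randomness flows from explicit seeds.
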