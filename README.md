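# htsnet

Network-based hit prioritization for genome-scale RNAi screens.

A high-throughput RNAi screen assigns every gene a z-score, but ranking
genes by z-score alone ignores that phenotypes are produced by pathways,
not isolated genes. `htsnet` re-prioritizes screening hits by searching two
gene networks — an undirected protein–protein **interactome** (including
TF–TF interactions) and a directed transcription-factor → target
**regulome** — for connected *subnetworks* whose average z-score is locally
maximal, validating them against three empirical null models, and merging
interactome and regulome findings into *meta-subnetworks* that span both
regulatory levels.

## Method

**Score.** A subnetwork *sn* is scored by the mean z-score of its members:

    S(sn) = (1/|sn|) · Σ_{g ∈ sn} z(g)

**Detection.** Every scored network node is tried as a seed. Neighbors of
the current subnetwork are tested independently: node *v* is aggregated iff

    S(sn ∪ {v}) − S(sn) > th

with improvement threshold `th = 0.05` by default. All accepted neighbors
of a layer are added simultaneously, then their unexplored neighbors form
the next layer (breadth-first); a rejected node closes its path for that
seed. Redundant results (mutual overlap ≥ 80%) are pruned, keeping the
higher-scoring subnetwork — except that a smaller subnetwork that scores
*higher* than a larger one containing it survives alongside it.

**Validation.** Each candidate receives three empirical p-values:
* **p-I** — against subnetworks detected after shuffling the
  score-to-gene assignment (does the score placement matter?);
* **p-II** — against subnetworks detected on degree-preserving rewired
  networks (does the specific wiring matter?);
* **p-III** — against mean scores of random gene sets of the same size
  (is the score high at all for its size?).

Null score samples are fitted with Gaussian mixtures (components chosen by
BIC) and p-values are mixture upper-tail probabilities, compared
size-matched. After Bonferroni correction over the candidate family, a
subnetwork is retained only if **all three** p-values pass the
per-network significance level.

**Integration.** Retained interactome and regulome subnetworks sharing at
least *n* genes are linked; connected bundles become meta-subnetworks.

**Enrichment.** Gene sets are tested for annotation-term
over-representation with the exact hypergeometric upper tail and
Benjamini–Hochberg FDR control (5% default).

## Worked example

`examples/run_synthetic_screen.py` generates a 300-gene synthetic screen
with an 8-gene planted module (z ~ N(3, 0.5) against an N(0, 1)
background), runs the full pipeline and prints:

```
planted module: G0056, G0059, G0145, G0148, G0180, G0194, G0201, G0267
interactome: 300 genes, 125 candidate subnetworks, 13 retained
regulome: 180 genes, 61 candidate subnetworks, 0 retained
meta-subnetworks at n=2: 0
top subnetwork: seed G0014, 8 genes, mean z = 2.944, p-values 0.0003/9.2e-06/5.3e-14
  contains 7/8 planted genes
outputs written to scratch_example_out/results (47 files, incl. HTML report)
```

The top retained subnetwork recovers 7 of the 8 planted genes; its three
Bonferroni-corrected p-values are all below the 0.01 threshold. The
regulome retains nothing here because the planted module lives in the
interactome and its genes are only scattered regulome targets. Other
examples: `expand_one_seed.py` (hand-traceable expansion on a 5-gene toy
graph), `null_distributions.py` (the three nulls and how a module
separates from them), `go_enrichment.py` (term enrichment with a
positive-control term).

The same pipeline is available from the shell:

```sh
htsnet fixtures --out screen/ --n-nodes 300 --module-size 8 --seed 46
htsnet run --scores screen/scores.tsv --interactome screen/interactome.tsv \
    --regulome screen/regulome.tsv --annotations screen/annotations.tsv \
    --th 0.05 --alpha-int 0.01 --alpha-reg 0.01 --min-common 2 \
    --seed 7 --out results/
```

## Input formats

All inputs are plain tab-delimited text: scores (`gene<TAB>z-score`,
optional header), edge lists (`source<TAB>target[<TAB>class]` with class
∈ {ppi, tf-tf, tf-target}; ppi and tf-tf edges route to the interactome,
tf-target to the regulome), an optional alias → canonical identifier
mapping, and optional `gene<TAB>term[<TAB>name]` annotations. Gene
identifiers are opaque strings; NCBI links are added in reports when they
are all-numeric (Entrez convention).

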