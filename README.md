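# cubkit

Codon usage bias (CUB) analysis toolkit for coding sequences: positional
nucleotide composition, RSCU, Wright's effective number of codons (ENC),
CAI / FOP / CBI, parity-rule-2 (PR2) coordinates, GC12~GC3s neutrality
analysis, ENC-vs-GC3s classification against the mutation-only reference
curve, hierarchical clustering of RSCU matrices, distance-based
neighbor-joining trees, and a synthetic CDS generator with controlled
GC3 pressure, codon selection and inter-species divergence.

## Layout

| module | what it does |
|---|---|
| `cubkit.codonio` | CDS FASTA reading/validation, genetic code, codon counting |
| `cubkit.composition` | A/T, G/C, per-base X3s, GC3s/AT3s, GC1s/GC2s/GC12 |
| `cubkit.cub_indices` | RSCU + cross-set means, ENC, CAI, FOP, CBI, optimal-codon derivation |
| `cubkit.bias_analysis` | expected-ENC curve, PR2 points, Pearson/neutrality, codon~GC3s matrices |
| `cubkit.clustering_phylo` | p-distance, neighbor joining, hierarchical clustering, Robinson–Foulds |
| `cubkit.synthetic_data` | seeded CDS/species-set simulation |
| `cubkit.pipeline` / `cubkit.cli` | end-to-end orchestration and the `cubkit` command |
| `cubkit.datasets` | bundled published per-species MMP-2/MMP-9 codon statistics |

## CLI

Every stage is a subcommand; outputs are TSV/Newick/JSON only, logs go to
stderr. Exit codes: 0 ok, 2 validation error, 3 stage failure.

```sh
cubkit simulate --seed 1 --n-codons 600 --gc3-pressure 0.65 -o genes.fasta
cubkit profile genes.fasta -o composition.tsv
cubkit rscu genes.fasta -o rscu.tsv --mean
cubkit indices genes.fasta -o indices.tsv
cubkit pr2 genes.fasta -o pr2.tsv
cubkit neutrality genes.fasta -o neutrality.tsv
cubkit encplot genes.fasta --out-points points.tsv --out-curve curve.tsv
cubkit cluster genes.fasta --out-newick rscu.nwk --out-merges merges.tsv
cubkit njtree aligned.fasta -o tree.nwk          # or --from-distances m.phy
cubkit fixtures --out-dir fixtures/ --seed 1
cubkit run-all --config config.yaml
```

`run-all` consumes a YAML config:

```yaml
gene_sets:
  mmp2: path/to/mmp2_species.fasta
  mmp9: path/to/mmp9_species.fasta
output_dir: out/
x3s_convention: per_base_denominator   # or simple
gc12_universe: synonymous              # or all
pr2_mode: fourfold                     # or all3
linkage: complete                      # or average
cai_floor: 0.01
aligned: true                          # also build an NJ tree
```

## Data availability

The per-species summary statistics bundled in `cubkit/data/` are published
values usable offline. The two yak coding sequences (GenBank MZ476247,
MZ476248) are not redistributed; to run the accession-based checks, fetch
them yourself, e.g.

```sh
efetch -db nuccore -id MZ476247 -format fasta_cds_na > data/accessions/MZ476247.fasta
efetch -db nuccore -id MZ476248 -format fasta_cds_na > data/accessions/MZ476248.fasta
```

## Conventions worth knowing

- Codons print in RNA alphabet in canonical codon-table order (stops
  last); DNA is used internally.
- The "s" statistics (GC3s, GC1s/GC2s by default, X3s) are computed over
  the 59 synonymous codons — sense codons of families with ≥ 2 members.
- The per-base X3s default divides each base count by the number of
  synonymous codons whose family could end in that base, so the four
  values may sum to > 1 (`x3s_convention: simple` partitions instead).
- ENC skips families with < 2 counted codons, imputes the 3-fold class
  from the 2- and 4-fold means when unobservable, and caps at 61.
- CAI requires reference weights; by default they are derived from the
  analysed set itself (RSCU / max RSCU per family), as is the optimal
  codon set (highest mean RSCU per family). Supply files to override.
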