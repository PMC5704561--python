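# phyloscope

Phylogenomic analysis of diverse gene families, built around four questions:

1. **How does a sprawling protein family cluster and relate?** Greedy
   identity/coverage clustering (BLASTCLUST-style single linkage),
   progressive multiple alignment with a gap-fraction/homogeneity column
   filter, iterative merging of similar clusters by profile–profile
   alignment score ratios, per-cluster neighbor-joining trees with bootstrap
   supports, a UPGMA dendrogram over the remaining cluster dissimilarities,
   and midpoint-rooted subtrees grafted onto its tips — one comprehensive
   family tree.
2. **How much of the family's history is horizontal?** Per-genome-pair
   patristic distances from the gene trees and from 16S-like marker trees,
   with sentinel distances (12 protein / 3 rRNA) for pairs split across
   never-aligned clusters and a shortest-distance rule for multi-copy
   genomes; Spearman rank correlation of the two columns quantifies
   coherence with vertical descent.
3. **What selection pressure acts on the family?** Pairwise Nei–Gojobori
   (NG86) dN/dS on back-translated codon alignments, summarized as
   per-group medians.
4. **What genomic context does each copy live in?** Classification into
   CRISPR-associated / solo / mobile-element categories from gene
   neighborhoods, adaptation-module arrangement typing, fusion detection,
   and genome-weighted presence summaries.

A synthetic-data module generates all inputs with known ground truth
(species tree, transfer/duplication/loss history, true dN/dS, true locus
categories), so every stage is validated by parameter recovery.

## CLI

```bash
phyloscope simulate --n-genomes 20 --hgt-rate 1.0 --seed 1 --out sim/
phyloscope cluster --identity 0.5 --coverage 0.8 sim/proteins.faa clusters.tsv
phyloscope align --in sim/proteins.faa --out aln.faa --mask-out mask.tsv
phyloscope tree --in sim/proteins.faa --bootstrap 100 --out tree.nwk
phyloscope coherence --protein-tree tree.nwk --rrna-tree rrna.nwk \
    --sentinels 12,3 --out pairs.tsv
phyloscope dnds --protein-aln aln.faa --cds sim/cds.fna --out dnds.tsv
phyloscope classify --features sim/features.tsv --window 10 --out classes.tsv
phyloscope run-all --config config.yaml --out results/
```

`run-all` accepts a YAML config mirroring the stage parameters (see
`phyloscope.pipeline.PipelineConfig`); with no config it simulates a small
demo data set. Exit codes: 0 ok, 1 user error, 2 internal error.

## Library layout

| module | contents |
| --- | --- |
| `phyloscope.synthetic_data` | Yule species trees, gene families with HGT (SPR transfers), duplication and loss, MG94/HKY codon simulation with controllable dN/dS, slow Jukes–Cantor rRNA markers, annotated feature tables |
| `phyloscope.sequence_io` | FASTA / Newick / feature-table readers and writers with strict validation |
| `phyloscope.cluster_align` | pairwise identity+coverage, greedy clustering, progressive alignment, column filter, frequency profiles |
| `phyloscope.family_tree` | profile–profile scoring, iterative cluster merging, UPGMA, neighbor joining + bootstrap, midpoint rooting, grafting |
| `phyloscope.coherence` | patristic distances, genome-pair tables with sentinel/min rules, Spearman coherence |
| `phyloscope.selection` | back-translation, NG86 dN/dS, group medians |
| `phyloscope.locus_context` | CAS / solo / MGE classification, arrangements, genome-weighted summaries |
| `phyloscope.pipeline` | end-to-end orchestration and reporting |

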