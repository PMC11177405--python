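# tubkit

Resolving a multi-isotype gene family (tubulins) in an allopolyploid
genome. The pipeline mines family members in an annotated genome by local
alignment, reconstructs ancestral-karyotype genomic blocks from labeled
syntelog anchors, detects cross-subgenome homeolog groups via collinear
chaining, classifies gene relations (homeolog / tandem paralog /
transposed paralog / homeoparalog / pseudogene), assigns isotypes by
cross-referencing NJ clades with genomic-context similarity and block
allocation, quantifies Ka/Ks with Nei–Gojobori (1986) counting, and
measures per-subgenome expression contributions including salt-stress
regulation calls.

A synthetic allohexaploid generator with full ground truth (three diverged
subgenomes, block-structured chromosomes, a multi-isotype family with
class-specific exon counts, post-polyploidy loss / pseudogenization /
tandem and transposed duplication, codon evolution at controlled Ka/Ks,
and biased tissue expression) stands in for a real genome, so every stage
is testable end to end with exact recovery oracles.

## Layout

| module                | role |
|-----------------------|------|
| `tubkit.core`         | genome/gene-model types, FASTA/GFF3/TSV I/O, CDS extraction, exon–intron structure, pseudogene diagnosis |
| `tubkit.simulate`     | synthetic allohexaploid generator + ground truth |
| `tubkit.mining`       | Smith–Waterman search (BLOSUM62, affine gaps, Karlin–Altschul E-values), hit filtering, conserved-motif scan |
| `tubkit.synteny`      | RBH anchors, MCScanX-style collinear chaining, homeolog groups, block-border inference, gene→block allocation |
| `tubkit.homology`     | relation classification, context similarity, isotype resolution, missing-ortholog report, gene naming |
| `tubkit.evolution`    | NG86 Ka/Ks, codon alignment, NJ trees, clade labeling, protein distances |
| `tubkit.expression`   | expression matrices, average-linkage heatmap order, subgenome contributions, salt regulation calls |
| `tubkit.pipeline`/`cli` | stage orchestration and the `tubkit` command |

Packaged data: `tubkit/data/inventory/*.tsv` — the reference inventory of
*Camelina sativa* tubulin genes (17 α, 34 β incl. 8 pseudogenes, 6 γ) with
NCBI GeneIDs; `tubkit/data/motifs/*.json` — motif-model fixtures derived
from the default synthetic reference proteins.

## CLI

```sh
tubkit simulate --seed 1 --out data/            # FASTA+GFF3+TSV+truth JSON
tubkit mine --fasta g.fa --gff3 g.gff3 --queries q.fa --out hits.tsv
tubkit synteny --fasta g.fa --gff3 g.gff3 --subgenomes s.tsv --out chains.tsv
tubkit blocks --anchors labeled_anchors.tsv --out blocks.tsv
tubkit evolve --kaks pairs.tsv --out kaks.tsv
tubkit express --matrix expression.tsv --subgenomes gene_sub.tsv --out contrib.tsv
tubkit report --seed 1 --out report.json        # simulate + full recovery
```

Exit codes: 0 success, 2 usage error, 3 data error.

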