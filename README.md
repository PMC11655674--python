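# sitescout

Transcription-factor binding-site discovery for bacterial genomes, built as
a reusable pipeline:

1. **DE filtering** — threshold a differential-expression table
   (|log2FC| ≥ 2, adjusted p ≤ 0.01 by default) and subtract a prior
   regulon gene list.
2. **Operon collapsing** — chain same-strand genes with intergenic gaps
   below 50 bp into transcriptional units.
3. **Promoter extraction** — one window per operon leader (300 bp upstream
   + 10 bp downstream of the start codon), strand-oriented.
4. **Orthology** — reciprocal-best-hit ortholog detection from affine-gap
   local protein alignment (BLOSUM62, gap 11/1; coverage ≥ 70 %,
   identity ≥ 35 %) and harvesting of ortholog promoter sets.
5. **Motif discovery** — ZOOPS (zero-or-one occurrence per sequence) EM
   with seeded restarts and phase-shift refinement; degenerate IUPAC
   consensus derivation; Monte-Carlo significance.
6. **PWM scanning** — log-odds scores with *exact* p-values computed by
   dynamic programming over an ε-discretized score axis; palindromic
   double hits are aggregated per region.
7. **Synthetic data** — generators for genomes with controllable operon
   structure, DE tables with exact threshold/overlap counts, planted-site
   promoter sets and diverged ortholog families, each with a ground-truth
   sidecar.

All coordinates are 0-based half-open internally (GFF3 I/O converts).
Every stochastic component takes an explicit seed and is reproducible.

## CLI

```sh
# synthesize a test bundle
sitescout simulate de-table --n-genes 4000 --n-de 381 --n-regulon-overlap 200 \
    --seed 1 --out-de de.tsv --out-regulon regulon.txt --out-truth truth.json
sitescout simulate genome --n-genes 4000 --gap 100 --seed 2 \
    --out-fasta genome.fasta --out-annotation ann.tsv

# individual stages
sitescout filter-de --de de.tsv --regulon regulon.txt --out genes.txt
sitescout operons --annotation ann.tsv --genes genes.txt --out operons.tsv
sitescout promoters --genome genome.fasta --annotation ann.tsv \
    --operons operons.tsv --out-fasta promoters.fasta --out-bed promoters.bed
sitescout discover --promoters promoters.fasta --width 22 --seed 0 \
    --out-meme motif.meme --out-json motif.json
sitescout scan --motif motif.meme --regions promoters.fasta \
    --p-cut 1e-4 --out-tsv hits.tsv --out-bed hits.bed
sitescout rbh --proteome-a a.fasta --proteome-b b.fasta --out pairs.tsv
sitescout classify-domains --scores data/domain_scores.tsv --out labeled.tsv

# everything at once (YAML config; flags override)
sitescout run --config config.yaml --seed 0
```

Motifs are exchanged in MEME minimal text format plus a JSON sidecar
(consensus, occupancy, log-likelihood ratio, approximate e-value).
Scan hits are written as TSV and BED6 (score = −10·log10 p, capped).

## Layout

```
src/sitescout/
  seq.py        sequences, IUPAC patterns, FASTA I/O
  regulon.py    DE filtering, operons, promoters, domain classification
  orthology.py  pairwise alignment, reciprocal best hits, promoter harvest
  motifs.py     PWM, ZOOPS EM discovery, consensus, significance, MEME I/O
  scan.py       exact score distributions, scanning, hit aggregation
  simulate.py   synthetic-data generators with ground truth
  pipeline.py   stage orchestration and JSON summary
  cli.py        click command line
data/           reference domain-score table used by tests and the CLI demo
tests/          unit, property (hypothesis) and acceptance tests
```
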