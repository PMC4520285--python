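# snepscan

Comparative epigenomics of yeast strains at single-nucleosome resolution.
From per-sample aligned read starts (MNase-seq and MNase-ChIP-seq, BED) and
a pairwise genome alignment, the pipeline:

1. **align** — builds *common uninterrupted regions* (CURs: alignable
   regions ≥ 4 kb in both strains with no indel > 30 bp) and translates
   coordinates bidirectionally between genomes.
2. **coverage** — 90-bp chunk coverage profiles over CURs, replicate QC,
   and PCA with permutation-based component significance.
3. **nucmap** — calls nucleosome dyads per replicate, classifies
   well-positioned vs fuzzy nucleosomes by replicate reproducibility,
   matches maps across strains (mutual nearest neighbour, ±75 bp), emits
   unaligned nucleosomal regions (UNRs), and flags positional divergence.
4. **snep** — extracts per-nucleosome counts, estimates DESeq-style
   median-of-ratios size factors, and detects single-nucleosome
   epi-polymorphisms (SNEPs) with a negative-binomial GLM
   likelihood-ratio test of the strain × assay interaction
   (Benjamini–Hochberg at FDR = 1e-4), plus MNase-only occupancy tests.
5. **genediv** — 600-bin gene profiles (250 × 10 bp upstream, 100
   TSS→TES percentile bins, 250 × 10 bp downstream), complete-linkage
   clustering of differential patterns, the *epidiv* ANOVA divergence
   statistic, δ-based gene selection, and a metaphenotype QTL scan with a
   10-permutation genome-wide threshold.
6. **covary** — mark correlation matrices, SNEP co-variation with Fisher
   enrichment, regionality randomization tests, and positional-class
   (+1/−1) enrichment tests.

A first-class `synthetic` module generates strain genomes (SNPs + indels),
nucleosome landscapes with planted shifts/evictions/fuzziness,
NB-distributed read starts with planted SNEPs, and segregant crosses with a
planted QTL — every stage is testable offline with known ground truth.

## CLI

```sh
# simulate a two-strain dataset (writes FASTA, BED reads, GFF3, blocks TSV,
# and a sample sheet)
snepscan simulate --config examples/sim.yaml --seed 1 --outdir sim/

# build CURs from an alignment-block table
snepscan curs --blocks sim/blocks.tsv --min-length 4000 --max-indel 30

# full pipeline (simulate-mode or file-mode config)
snepscan run --config pipeline.yaml

# single stages (run the pipeline up to that stage)
snepscan coverage --config pipeline.yaml
snepscan nucmap   --config pipeline.yaml
snepscan snep     --config pipeline.yaml
snepscan genediv  --config pipeline.yaml
snepscan covary   --config pipeline.yaml

# QTL scan from TSV inputs
snepscan qtlscan --values values.tsv --genotypes genotypes.tsv --seed 1
```

A file-mode pipeline config:

```yaml
seed: 1
outdir: out/
sample_sheet: sim/samples.tsv   # path, strain, assay, mark, replicate
blocks: sim/blocks.tsv          # alignment blocks (see below)
genes: sim/genes.gff3
contig_lengths: {S1: 60000, S2: 60000}
thresholds: {chunk: 90, min_cur_length: 4000, max_indel: 30, fdr: 0.0001}
```

Simulate-mode replaces the file keys with a `simulate:` section (see
`tests/test_cli.py` for a complete example). All outputs are TSV/BED/GFF3
plus a `manifest.json` recording parameters, seeds and input checksums;
reruns with the same config are byte-identical.

### Alignment-block table

A TSV with header `source_contig source_start source_end target_contig
target_start target_end variants`, coordinates 0-based half-open, and
variants encoded `offset:type:size` (comma-separated; type ∈ snp/ins/del,
offsets relative to the block's source start). The synthetic module writes
this format directly; MUMmer-style coordinates can be converted to it.

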