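# dirtseq

Detection of dicistronic tRNA–mRNA transcripts from short-read RNA-seq
alignments, for any annotated genome.

A dicistronic tRNA–mRNA is a single transcript carrying a tRNA and an
adjacent protein-coding mRNA. Its read signature is continuous sequencing
coverage across the intergenic gap between the two genes. `dirtseq`
assembles tRNA/protein-coding-gene pairs from annotations, counts reads
and computes per-base coverage from alignments, and classifies each pair
per biological group by

1. expression filters (tRNA raw count ≥ 1, gene raw count ≥ 10 by
   default; gene counting uses a mapping-quality ≥ 10 filter, tRNA
   counting keeps multi-mapped reads),
2. a paired one-sided t-test per pair comparing intergenic mean coverage
   against each of the two introns closest to the gap, across biological
   replicates, with Benjamini–Hochberg FDR (q < 0.05) pooled over all
   contrasts in the run,
3. a directionality check on replicate-merged coverage (intergenic mean
   above every tested intron mean), and
4. a continuity check (every intergenic base covered by ≥ 1 read in the
   merged alignments).

A synthetic-data module generates format-faithful GFF3 + BED6 + SAM
datasets with planted dicistronic loci and a truth table, so the entire
pipeline is testable without any external data.

## Modules

| module                    | contents |
| ------------------------- | -------- |
| `dirtseq.intervals`       | 0-based half-open `GenomicInterval` primitive |
| `dirtseq.genome_model`    | GFF3/BED6 parsing, intron derivation, pair assembly with overlap exclusion |
| `dirtseq.coverage_engine` | SAM/BAM ingestion, two counting policies, per-base coverage, bedGraph/count-matrix writers |
| `dirtseq.dirt_core`       | expression filters, contrast t-tests, BH adjustment, continuity check, verdicts |
| `dirtseq.simdata`         | seeded dataset simulator, scenario presets, packaged 19-row grapevine candidate table |
| `dirtseq.summarize`       | CPM/logCPM, component Pearson correlations, candidate-table summaries, set-partition reports |
| `dirtseq.cli`             | `dirtseq` command-line entry point |

## CLI

```sh
# simulate a dataset (annotation + per-replicate SAM + truth table)
dirtseq simulate --config sim_config.json --seed 7 --out simdir/

# assemble candidate tRNA/gene pairs
dirtseq pairs --gff annotation.gff3 --bed trna.bed --out pairs.tsv

# run detection; groups.tsv has columns group_id, replicate_id, path
dirtseq detect --gff annotation.gff3 --bed trna.bed --groups groups.tsv \
    --fdr 0.05 --trna-min 1 --pcg-min 10 --mapq 10 \
    --out calls.tsv --bed-out candidates.bed

# summarize a candidate table (defaults to the packaged table)
dirtseq summarize --out summary.json

# correlate component expression matrices (candidate x group TSVs)
dirtseq correlate --trna trna.tsv --intergenic inter.tsv --pcg pcg.tsv \
    --out correlations.tsv
```

`detect` writes one row per pair per group with per-contrast p/q values,
direction and continuity flags and a verdict (`dicistronic`,
`rejected_expression`, `rejected_test`, `rejected_direction`,
`rejected_continuity` or `untestable`), plus a JSON run manifest with
the configuration and input digests.

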