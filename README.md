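# tyshuffle

Simulation and analysis of retrotransposon-mediated genome rearrangements in a
hybrid diploid yeast genome.

The package models a diploid formed from two sequence-diverged haploid parents
(`W` and `Y`), heterozygous for ~55,000 SNPs and carrying asymmetric Ty1/Ty2
retrotransposon complements. Double-strand breaks targeted to Ty1 elements
drive non-allelic homologous recombination; `tyshuffle` simulates the
resulting karyotypes, synthesizes the read-depth and long-read signals such
events leave, and calls, classifies, and quantifies them.

## Modules

| module | role |
| --- | --- |
| `tyshuffle.genome_model` | chromosome/SNP/element definitions, default hybrid genome, TSV/BED serialization |
| `tyshuffle.synthetic_data` | karyotype operations (pop-outs, unequal crossovers, circles, isochromosomes, inversions, translocations, allelic LOH, aneuploidy), per-SNP read-count synthesis, long-read matrices, fluctuation assays |
| `tyshuffle.event_caller` | ratio-of-coverage normalization, dosage segmentation, event taxonomy (I-/T-LOH, I-/T-DEL/DUP, CIRCLE, ISO, MONOSOMY/TRISOMY/UPD), breakpoint windows, haploid PCR classes |
| `tyshuffle.ty_association` | breakpoint/element overlap, partner-family tallies, binomial hotspot test |
| `tyshuffle.interaction_stats` | pair enumeration, chi-square goodness of fit, Fisher exact, region chi-square (Yates), binomial bias tests |
| `tyshuffle.rate_estimation` | Lea–Coulson method of the median, per-division rates, fold changes |
| `tyshuffle.ty_breakpoint_mapper` | two-thirds SNP voting, conversion-tract location and sidedness, mechanism labels |
| `tyshuffle.cli_pipeline` | `tyshuffle` command-line entry points |

## CLI

```sh
tyshuffle simulate --seed 7 --n-isolates 19 --events-per-isolate 3 \
    --profile mini --out run/
tyshuffle call --counts run/counts_00.tsv --genome-dir run/ --out run/events.json
tyshuffle associate --events run/events.json --genome-dir run/ --out-dir run/
tyshuffle stats --out run/stats.json
tyshuffle rates --events-tally tally.json --out run/rates.json
tyshuffle map-ty --matrix run/tymatrix.tsv --out run/tract.json
```

`simulate` writes the genome (`chromosomes.tsv`, `ty.bed`, `snps.tsv`), one
`counts_*.tsv`/`truth_*.tsv`/`karyotype_*.json` trio per isolate, and a
checksum manifest; every stage is deterministic for a given seed.

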