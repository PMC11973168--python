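# skewdomain

Tools for quantifying how regulatory-element activity relates to cohesin
recruitment on diploid genomes:

- **Allelic skew** — haplotype-resolved read counting at phased heterozygous
  SNVs, alignment-bias zeroing, exact binomial (or beta-binomial) skew tests,
  extreme-skew region selection, and a genotype-group meta-analysis with
  paired t-tests.
- **Spike-in calibration** — per-sample ChIP down-sampling factors
  (`α × 1/spikein_ChIP × spikein_Input/target_Input`, with α scaling the
  largest factor to exactly 1), seeded read subsampling, and RPKM tracks.
- **Domain quantification** — length-normalized inside/outside coverage
  ratios, a deterministic threshold peak caller, rule-based CRE
  classification, and scanning for long "neutral" intervals inside
  A-compartment chromatin.
- **Genome editing** — personalized (per-haplotype) genome construction from
  phased VCFs with exact coordinate maps, insertion-edited genomes with
  junction breakpoints, in-silico DpnII digestion, and viewpoint selection.
- **Junction analysis** — classification of reads at an insertion locus into
  junction-spanning / internal / flank categories with a support summary.
- **Motif analysis** — log-odds PWM scanning on both strands, CTCF motif
  orientation labels, and exact-test motif enrichment of up- vs down-skewed
  allele sequence sets.
- **Synthetic data** — a fully seeded generator for diploid donor cohorts,
  activity-coupled coverage, spike-in mixtures, and edited-locus reads, so
  the entire pipeline is testable without external data.

All coordinates are 0-based half-open internally; VCF positions and printed
`chrom:start-end` region strings are 1-based inclusive and converted at the
parsing boundary.

## CLI

The `skewdomain` entry point groups one subcommand per stage:

```sh
skewdomain io validate peaks.bed
skewdomain simulate --config cfg.toml --outdir cohort/
skewdomain edit apply --ref ref.fa --edit edit.toml --out edited.fa
skewdomain digest --fa locus.fa --enzyme GATC --min 1000 --max 3000 --viewpoints 6
skewdomain skew --hap1 h1.tsv --hap2 h2.tsv --vcf phased.vcf --peaks peaks.bed --out skew.tsv
skewdomain calibrate --totals totals.tsv --seed 7 --out factors.tsv
skewdomain ratio --bedgraph rep1.bedgraph --bedgraph rep2.bedgraph \
    --inside "chr11:32,188,452-32,249,902" --outside "chr11:32,300,054-32,391,239"
skewdomain neutral --compartments A.bed --exclude H3K9me3.bedgraph --chrom chrX
skewdomain classify --signals '{"H3K4me3": 10, "H3K4me1": 2, "H3K27ac": 3, "CTCF": 0}'
skewdomain motifs --up up.fa --down down.fa --pwm motifs.meme --out enrichment.tsv
skewdomain junctions --placements reads.tsv --insert "chrX:1001-1325"
```

Read placements are plain TSV tables
(`read_id, genome, chrom, start, end, mate_start, mate_end, source`);
coverage interchange is bedGraph; motifs use the MEME minimal format.

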