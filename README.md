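# crossase

Allele-specific expression (ASE) meets selective-sweep scanning for F1
crosses of two divergent lines.

Given parental and F1 genotypes (VCF), RNA alignments (text SAM) or
pre-made allele-count tables, and gene models (GFF3), the pipeline:

1. **discriminates** the parental lines' alleles — sites where every
   line-A parent is homozygous for one allele and every line-B parent
   for the other (strict mode; a frequency-contrast mode is available),
   after removing sites with QUAL < 30 — and annotates each SNP
   (exonic / splice region / intronic / upstream / downstream /
   intergenic, with synonymous / nonsynonymous / stopgain / stoploss
   calls inside CDS);
2. **scans for sweeps** over the two parental populations: windowed
   Weir–Cockerham Fst (window estimate = Σa / Σ(a+b+c)) and pooled
   heterozygosity Hp = 2·Σn_maj·Σn_min/(Σn_maj+Σn_min)² per population,
   Z-standardized genome-wide; the top 1% high-ZFst and low-ZHp windows
   are merged into candidate regions and overlapped with genes;
3. **detects ASE** at F1-heterozygous discriminating SNPs: allele counts
   from the CIGAR-walked alignments (MAPQ/baseq/flag filtered),
   technical replicates pooled, depth-gated (each allele ≥ 20 reads,
   total ≥ 50), tested with an exact two-sided binomial test against
   0.5, BH-adjusted per tissue, and called ASE when q < 0.05 AND the
   line-A ratio is > 0.7 or < 0.3; gene-level calls exclude known
   imprinted genes;
4. **intersects** ASE genes with sweep-region genes into *core* genes
   and compares ASE-vs-other gene expression (FPKM > 0.01, rank-sum
   test).

A fully truth-labelled synthetic data generator (`synthetic_data`)
plants divergent allele frequencies, low-Hp/high-Fst sweep windows,
cis-regulatory imbalance (beta-binomial allele counts) and imprinted
near-monoallelic genes, and can emit the entire dataset as standard
files (VCF / SAM / GFF3 / TSV) for end-to-end validation.

## Command line

```sh
crossase simulate --seed 7 --outdir data/              # synthetic dataset
crossase run-all  --seed 7 --outdir run/               # simulate + full pipeline + reports

# or stage by stage on an existing dataset:
crossase discriminate --parents-vcf data/parents.vcf --pop-map pops.tsv \
    --gff data/genes.gff3 --out disc.tsv
crossase sweep --vcf data/parents.vcf --pop-map pops.tsv --gff data/genes.gff3 \
    --window 150000 --step 75000 --top 0.01 --out-prefix scan/
crossase ase --counts-dir data/counts --snps disc.tsv --f1-vcf data/f1.vcf \
    --imprinted data/imprinted.txt --gff data/genes.gff3 --out-prefix ase/
crossase core --ase ase/ase_genes.tsv --regions scan/regions_genes.tsv \
    --fpkm data/fpkm.tsv --out-prefix core/
```

`--pop-map` is a two-column TSV mapping sample names to population
labels (`YUNLING` / `NUBIAN`). `crossase ase` also accepts
`--sam-manifest` (TSV: individual, tissue, replicate, path) to count
alleles directly from text SAM files.

## Layout

| module | contents |
| --- | --- |
| `crossase.io_formats` | VCF / SAM / GFF3 / BED / TSV readers and writers (internal coordinates 0-based half-open) |
| `crossase.synthetic_data` | `SimulationConfig`, truth tables, generators, `write_dataset` |
| `crossase.discriminating_variants` | QUAL filter, strict/frequency discriminating-SNP assignment, annotation, coding-change classification, Ts/Tv |
| `crossase.sweep_scan` | Weir–Cockerham components, window Fst/Hp, Z-transform, extreme-window selection, region merging, gene overlap |
| `crossase.ase_detection` | allele counting, replicate pooling, depth gates, binomial test, BH, site/gene ASE calls, imprinted exclusion, tissue overlap |
| `crossase.core_ase` | core-gene intersection, expression comparison, report bundle |
| `crossase.pipeline` | array-backed orchestration, dataset-directory runner, truth-based evaluation |

## Conventions and noteworthy behaviour

- QUAL 30.0 is kept (the filter removes strictly `QUAL < 30`); a ratio
  of exactly 0.7 is never called ASE; counts of (25, 25) pass the
  depth gate, (19, 40) does not.
- The literal reading of the depth filter (each allele ≥ 20 reads)
  caps the detectable imbalance at (T−20)/T for total depth T, so
  near-monoallelic (imprinted-like) sites are silently filtered at
  moderate depth; `filter_counts(mode="major")` relaxes this.
- Low-ZHp selection takes the lower tail (lowest heterozygosity), not
  |ZHp|; window geometry (150 kb / 75 kb step by default) and the top
  fraction are parameters.
- All simulation outputs are pure functions of the config (seed
  included): rerunning a config reproduces every file byte for byte.
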