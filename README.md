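# purplemap

Two-bulk Euclidean-distance (ED) trait mapping for an F1 pseudo-testcross,
with a synthetic data generator so the whole analysis runs without any
external download. The pipeline covers:

- **simdata** — F1 population simulation (Haldane recombination, liability
  threshold phenotype model calibrated to expected extreme-class counts of
  18 green / 32 dark purple at n = 127), extreme-bulk selection, pooled
  sequencing-depth simulation for a DNA (BSA) and an expression-weighted RNA
  (BSR) variant layer, negative-binomial pooled expression counts with
  planted DEGs, and promoter InDel allele/primer fixtures (default 181-bp
  insertion between promoter positions −332 and −152).
- **bsa** — per-variant ED between the two bulks' allele-frequency vectors,
  ED⁴ powering, tricube smoothing along chromosomes, threshold-based
  candidate-region calling (robust median+MAD rule by default; median+SD
  available), and interval→gene overlap.
- **de** — median-of-ratios normalization (fixed-scale anchored), Welch's
  t-test on log2 counts, strict |log2FC| > 1 and P < 0.05 DEG filter with BH
  q-values reported, PCA sample scores, qPCR direction concordance.
- **integrate** — three-set Venn partition (BSA ∩ BSR ∩ DEG triple
  intersection flags prime candidates), pathway filtering, hypergeometric
  over-representation with BH correction, Pearson correlation network with
  a focal-gene report (|r| ≥ 0.8 and p < 0.05 by default).
- **assays** — anthocyanin content from absorbance readings
  ((A·V·n·465.2)/(ε·m) with A = (A530−A620) − 0.1(A650−A620); ε is a
  required user input with no default), 2^−ΔΔCt relative expression,
  antisense-oligo GC/binding-energy filtering, exact-match in-silico PCR,
  marker/phenotype co-segregation (Fisher exact), and IUPAC cis-element
  scanning in promoter coordinates.
- **pipeline** — orchestration with per-stage seeds derived from one global
  seed, hashed output manifests, and a truth-file recovery report.

## CLI

```sh
purplemap simulate --out sim/ --seed 7            # VCFs, GFF3, counts, fixtures, truth.json
purplemap bsa --vcf sim/bsa_pools.vcf --gff sim/genes.gff3 --out bsa/
purplemap bsa --vcf sim/bsr_pools.vcf --gff sim/genes.gff3 --out bsr/
purplemap de --counts sim/counts.tsv --classes sim/classes.csv --out de/
purplemap integrate --bsa bsa/genes.tsv --bsr bsr/genes.tsv --de degs.txt --out integrate/
purplemap assay ddct --ct ct.csv --reference GAPDH --calibrator GP1 --out ddct.csv
purplemap run-all --config run.yaml --seed 7 --out results/
```

`run.yaml` mirrors the dataclass knobs (`cross`, `bulk`, `expr`,
`analysis`, `stages`); every omitted key falls back to the documented
default and is echoed into `results/manifest.json` together with a SHA-256
hash of every output file.

## Conventions

Genetic positions are simulated in cM and emitted at 1 cM = 1 Mb. VCF
positions are 1-based; BED output is 0-based half-open; GFF3 is 1-based
inclusive. Promoter coordinates place −1 immediately 5′ of the ATG, with
inclusive intervals.
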