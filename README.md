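# famscan

Balancing-selection scan of gene families in multi-strain haploid variant
panels, plus factorial expression analysis — with a synthetic-data generator
so every stage is verifiable end to end without external downloads.

The toolkit covers:

- **simpanel** — coalescent haplotype simulators (neutral / balanced
  two-class / star genealogies), a multi-strain SNP panel generator with an
  embedded gene family segregating as a few diverged haplotype classes, and
  factorial / time-series expression simulation. Ground-truth tables are
  emitted for round-trip testing.
- **variants** — VCF (haploid or homozygous-diploid) and BED/GFF3 readers,
  per-gene per-strain SNP counting, per-gene haplotype matrices.
- **selscan** — Watterson's θ, nucleotide diversity π and Tajima's D from
  first principles (pairwise deletion with renormalization under
  missingness), genome-wide per-gene scan, nearest-rank top-decile flagging.
- **famtest** — per-strain 1-df chi-square test of family vs genome-wide
  variation with Benjamini–Hochberg FDR control.
- **haplogroup** — rescaled mismatch distances and complete-linkage
  grouping of strains into discrete haplotype classes; conserved/variable
  gene classification.
- **exprmod** — log2-ratio transform, PCA variance decomposition, factorial
  OLS with sequential-SS F tests and per-term FDR, spot-to-gene
  aggregation, time trends, hypergeometric enrichment (Bonferroni), qPCR
  reference normalization.
- **cli / pipeline** — subcommands and a deterministic
  simulate-then-analyze report bundle.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the statistical acceptance battery
(simulator calibration, oracle equivalence, power checks); the rest are
per-module unit and property tests.

## CLI

```sh
famscan simulate --n-strains 50 --n-genes 200 --seed 1 --out run/
famscan scan-td --vcf run/panel.vcf --genes run/genes.bed \
    --family-list run/family.tsv --quantile 0.9 --out run/tajima.tsv
famscan family-test --vcf run/panel.vcf --genes run/genes.bed \
    --family-list run/family.tsv --family fam --fdr 1e-4 --out run/fam.tsv
famscan haplogroup --vcf run/panel.vcf --genes run/genes.bed \
    --gene g0066 --cut 0.2 --out run/hap.tsv
famscan expr-fit --expr run/expression.tsv --meta run/expression_samples.tsv \
    --model GxT --fdr-g 0.05 --fdr-t 0.1 --out run/fits.tsv
famscan report --out run/ --seed 1
```

Exit codes: 0 ok, 2 config error, 3 data error. Identical config + seed
produce byte-identical output bundles.

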