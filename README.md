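# paleokin

Ploidy, kinship and clinical-variant screening for low-coverage ancient
DNA, plus a synthetic-data generator that makes every method testable
without real sequence data.

Ancient shotgun genomes commonly yield 0.01–2x coverage — far too little
for diploid genotype calling.  Standard practice represents each
individual by *pseudohaploid* calls (one randomly sampled allele per
covered site) over a fixed SNP panel such as the 1240k capture set.
`paleokin` implements three analyses that operate directly in this
regime, for archaeogeneticists characterizing cohorts of skeletal
remains:

- **ZAC (Z-score-Adjusted Coverage)** — per-chromosome copy number,
  genetic sex and aneuploidy calling.  For chromosome *c* with *r_c*
  reads over *s_c* panel sites, the normalized ratio is

  ρ_c = (r_c / s_c) / (Σ_auto r / Σ_auto s),

  which is 1.0 for a diploid autosome at any coverage.  A panel of
  karyotypically normal reference genomes (declared XX or XY) supplies
  mean and SD of ρ_c, with X/Y stored per copy; the copy estimate is
  round(k_ref · ρ_c / ρ̄_c) and autosomal departures from 2 copies are
  flagged when |z| = |ρ_c − ρ̄_c|/σ_c exceeds a threshold (default 3).
  Because the statistic is a ratio of rates, calls remain reliable down
  to ~0.01x mean coverage.

- **MPMR (Modified Pairwise Mismatch Rate)** — relatedness degree
  between sample pairs.  The raw PMR is the fraction of jointly covered
  SNPs whose pseudohaploid calls disagree; its expectation is
  (1 − φ)·B, with φ the kinship coefficient and B the unrelated-pair
  rate.  Dividing by B (cohort median, or a supplied value) gives a
  normalized score with expectations 0.5 / 0.75 / 0.875 / 1.0 for
  identical genomes, first-degree, second-degree and unrelated pairs;
  classification cuts at 0.625, 0.8125 and 0.90625, with a 20 Mb block
  jackknife for uncertainty and a relatedness network of degree ≤ 2
  edges.

- **Damage-aware panel screening** — pileup evidence matched against
  variant panels (a ClinVar-style clinical set, a pigmentation SNP set,
  mtDNA disease sites).  Post-mortem deamination mimics C→T/G→A
  transitions, so transition hits with fewer than `min_alt_reads`
  (default 2) supporting reads are excluded unless the same allele
  appears in a second sample or an explicit phenotype corroboration is
  supplied; transversions are never excluded by this filter.

The **synthetic-data generator** produces the matching inputs with known
truth: gene-dropped pedigree genotypes (Hardy–Weinberg founders, random
allele transmission), pseudohaploidization with tunable deamination and
error rates, Poisson per-chromosome depth tables under any karyotype
(`"XY"`, `"XX+21"`, `"XYY"`, …) and per-site pileups.

## Worked example

```sh
python examples/ploidy_demo.py
```

simulates 20 reference genomes at 0.1x and one XYY individual at 0.01x,
and prints:

```
sample mean coverage: 0.0100x
chrom  ratio    z       copies
    1  1.012    +0.92  2
   21  0.926    -2.77  2
    X  0.491    +...   1
    Y  1.031    +...   2

karyotype: XYY  genetic sex: M
```

The autosomal ratios hover around 1.0 (two copies); the X ratio sits at
one per-copy unit and the Y at two, so the sample is called XYY — the
configuration reported for one Bronze Age child burial (Jacob's
syndrome).  `examples/kinship_demo.py`, `examples/screen_demo.py` and
`examples/pipeline_demo.py` walk through the other capabilities the same
way; the pipeline demo recovers every planted truth (karyotype, kinship
edges, retained variant) from one declarative config.

A thin CLI wraps the same functions:

```sh
paleokin ploidy  --depths sample.tsv --refs refs.tsv --ref-karyotypes refk.tsv --out karyotype.tsv
paleokin kinship --geno prefix --out pairs.tsv --network edges.tsv
paleokin screen  --pileup cohort.tsv --panel clinical --out hits.tsv
paleokin run     --config demo.yaml --outdir out/
```

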