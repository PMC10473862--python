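# Methods

This note records the models behind `paleokin`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Pseudohaploid genotypes

All genotype handling assumes the low-coverage ancient-DNA convention:
one randomly sampled allele per covered site, encoded in EIGENSTRAT
reference-allele counts restricted to {0 = hom-alt, 2 = hom-ref,
9 = missing}.  A heterozygous `1` on input is recoded to missing with a
warning; simulator truth data may opt into the full diploid encoding.
Coordinates are 1-based GRCh37 throughout, chromosome labels normalized
to {1..22, X, Y, MT}.

## ZAC: coverage-ratio ploidy estimation

**Model.**  Reads over panel sites on chromosome *c* are treated as a
Poisson process with rate proportional to site count × coverage × copy
number.  The per-chromosome ratio ρ_c = (r_c/s_c)/(Σr/Σs over
autosomes) cancels the sample's overall coverage, so the only remaining
signal is copy number (site-weighted autosomal mean of ρ is exactly 1
by construction; the test suite asserts this to 1e-12).

**Reference statistics.**  ≥2 declared-normal genomes (any mix of XX
and XY) provide mean and SD of ρ_c per chromosome.  Gonosomal ratios
are divided by the declared copy number before pooling, so a single
per-copy expectation (≈0.5 under this normalization) serves any test
karyotype; XX genomes contribute nothing to Y and a reference set
without ≥2 usable contributions for a chromosome is refused.  Zero
reference variance is refused rather than patched, with a message
suggesting more references.

**Calls.**  Autosomes: copies = round(2ρ_c/ρ̄_c), z = (ρ_c − ρ̄_c)/σ_c,
flagged aneuploid iff copies ≠ 2 *and* |z| > 3.  The threshold 3 is the
conventional outlier bound: with 24 statistics per genome it keeps the
expected number of false flags per genome well below one at reference
noise levels.  Gonosomes: copies = round(ρ_c/ρ̄1_c) against the
per-copy mean; the z reported is the residual against the estimated
copy count scaled by √copies (Poisson variance grows with copy number).
The aneuploidy *flag* is reserved for autosomes, because "expected copy
number" for X/Y is undefined until the sex is known; gonosomal
anomalies are read off the assembled karyotype string instead
(`"X"·nX + "Y"·nY`, with `X0` for a single X).  Exact rounding halves
resolve toward 2 copies on autosomes and toward 1 copy on gonosomes —
conservative in both cases.  Genetic sex is M iff ≥1 Y copy, F iff
XX/XXX; X0 is reported as gonosomal X0 with sex left undetermined.
Fewer than 100 combined X+Y reads (default `min_reads`) yields
`undetermined` rather than a guess; 100 reads keep the binomial error
of the X:Y split below one copy unit.  Degenerate inputs never raise in
`call_karyotype`.

**Operating floor.**  On a 1240k-like map (~1.15M sites apportioned by
GRCh37 chromosome length) with 20 simulated references at 0.1x, ≥95% of
replicates per karyotype in {XX, XY, XYY, XXY, X0, trisomy 21} are
called correctly at 0.01x, and accuracy rises with coverage; at 0.005x
the smallest autosomes (≈90 reads on chromosome 21) begin producing
false copy-number departures.  These sizes (50 replicates per
karyotype, the coverage grid {0.005, 0.01, 0.02, 0.05}) are the
package's standard validation configuration.

Not modelled: GC/mappability correction (an extension point), segmental
or mosaic CNVs, contamination.

## MPMR: normalized pairwise mismatch

**Statistic.**  For samples a, b: overlap = sites non-missing in both;
PMR = mismatches/overlap, pooled site-wise across the genome (no
windowing).  Under random-allele pseudohaploidization the probability
two sampled alleles disagree is (1 − φ)·B, where φ is the kinship
coefficient and B the unrelated-pair mismatch rate of the population.
The normalized score PMR/B̂ therefore estimates 1 − φ with expectations
1, 0.875, 0.75, 0.5 for unrelated, second-degree, first-degree and
identical genomes.  Monozygotic twins are indistinguishable from a
duplicated sample; dizygotic twins are full siblings (first degree).

**Background.**  B̂ defaults to the median PMR of all pairs with
sufficient overlap, which assumes a mostly unrelated cohort.  When more
than half of the eligible pairs sit below the unrelated cutoff relative
to the upper decile of the PMR distribution, the median is likely
contaminated and a warning recommends supplying an external unrelated
rate.  (The check is made on raw PMRs because a contaminated median
shifts the normalized scores of truly related pairs toward 1,
hiding exactly the problem it should reveal.)

**Classification.**  Cutoffs 0.625 and 0.8125 are midpoints of adjacent
expected scores; the unrelated bound 0.90625 is the second/third-degree
midpoint, so third-degree pairs fall into "unrelated" rather than
inflating "second".  Intervals are closed below, open above, making
ties deterministic.  `min_overlap` defaults to 1,000 SNPs (binomial SE
of PMR ≈0.014 there, marginal against the ≈0.03 class spacing in PMR
units); below it the pair is `insufficient`.  No first-degree subtype
(parent–offspring vs siblings) or parental-sex resolution is attempted.

**Uncertainty.**  Delete-one-block jackknife over contiguous 20 Mb
windows by SNP coordinate (robust to linkage); empty blocks are
dropped, the last block per chromosome may be short, and fewer than two
non-empty blocks reports the SE as missing while the degree is still
assigned from the point estimate.

Validated properties (all in the test suite): scores within ±0.02 of
1 − φ at 50k overlapping sites; ≥95% correct degree over 100 simulated
pairs per class at 10k overlap; invariance to sample/SNP permutation;
robustness to 50% missingness; and stability of the normalized score
under 3% deamination damage applied to the whole cohort (the background
absorbs it).

## Damage-aware screening

A hit is any (sample, panel site) with read evidence; `no_call` iff no
alternate read.  The retention rule mirrors ancient-DNA practice:
transitions with fewer than `min_alt_reads` (default 2 — a single read
is the canonical damage suspect) are excluded unless the same panel
allele has alternate evidence in ≥2 samples (`multi_sample_corroborated`)
or a per-hit `(sample, rsID)` override stands in for phenotype evidence
such as diagnostic skeletal features (`phenotype_corroborated`).  An
optional `min_depth` additionally requires total depth for transitions.
Transversions cannot arise from deamination and are never excluded by
this filter.  The filter recomputes all flags from raw evidence, hence
is idempotent, monotone in `min_alt_reads`, and leaves transversion
status invariant.  A pileup record whose reference allele contradicts
the panel's indicates a coordinate/build problem and is skipped with a
warning rather than treated as evidence.

With 3% damage and 0.5x coverage over 5,000 transition panel sites and
no true variants, the expected number of falsely retained transitions
per sample at the default threshold is below one (asserted empirically
over seeds).

The shipped clinical, pigmentation (58-SNP) and mtDNA panels are
synthetic demonstration sets — format-identical, anchored on well-known
variants, but not a curated release.  A real clinical panel comes from
a ClinVar export filtered to pathogenic/likely-pathogenic SNVs with
deletions, duplications, CNVs and conflicting reports removed.
Pigmentation screening reports genotypes only; phenotype prediction
models are out of scope, as are genotype likelihoods, imputation and
haplotype-based analyses.

## Synthetic-data model

* **Gene dropping.**  Founder genotypes are Hardy–Weinberg with the
  reference-allele frequency drawn per site from U(0.05, 0.95) —
  avoiding near-fixed sites that carry no mismatch information; each
  child inherits one uniformly chosen allele per parent per site;
  duplicate ids are bit-identical genomes.  Kinship coefficients for
  arbitrary pedigrees come from the standard recursive (tabular)
  method, so simulated truth and theory are always available together.
* **Pseudohaploidization.**  Sites are covered independently with
  probability min(coverage, 1) — the single-read regime appropriate to
  sub-1x shotgun data.  Deamination converts a sampled C to T (G to A)
  with probability `damage_rate`, uniformly along the molecule (no
  read-terminal position model, a deliberate simplification of
  half-UDG chemistry); a damaged base matching neither site allele is
  discarded as tri-allelic.  `error_rate` flips the final call.
* **Depth and pileups.**  Per-chromosome reads are
  Poisson(sites × coverage × copies/2); per-site pileup depths are
  Poisson(coverage) with the same damage chemistry applied per read.
* **Determinism.**  Every generator takes a seed or Generator;
  identical inputs give bit-identical outputs (asserted in the suite).

Not emulated: linkage/recombination (sites are i.i.d., so IBD-segment
methods cannot be tested against this generator — sufficient for the
expectation-based statistics here), contamination mixtures,
reference-bias, sequence-level reads.  Passing tests therefore
demonstrate correctness of the statistics under the stated sampling
model, not robustness to every artifact of real libraries.

## Pipeline and reporting

`run_pipeline` executes simulate → ploidy → kinship → screen → report
from one declarative config; inputs for every enabled stage are
validated before anything runs, per-stage RNG streams are derived from
the config seed, and artifact SHA-256 digests are logged so identical
configs demonstrably reproduce identical bytes.  Cohort summaries
report the male percentage as floor(100·M/(M+F)) over determinate calls
— the convention that renders 15 males of 19 sexed individuals as 78%.
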