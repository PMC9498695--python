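# Methods

This note documents the models and estimators implemented in `selsweep`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter for
reproducing results.

## Data model

All statistics operate on a biallelic-SNP dosage matrix (sites × samples,
ALT-allele counts 0/1/2, missing = −1) parsed from VCF v4.x with GT
genotypes. Phase is discarded ("0|1" ≡ "0/1"). Multi-allelic records and
indels are excluded from the matrix but retained as variant records for
the indel-length and annotation summaries. Inputs are assumed pre-filtered
for call quality; the only site filter provided is a maximum-missingness
fraction (default 1.0 = off). On-disk coordinates are 1-based inclusive
(VCF/GFF3 convention); window arithmetic is half-open 0-based internally
and converted at the I/O boundary.

## Diversity

Per-site diversity is the unbiased mean pairwise haplotype difference
π = 2k(n−k)/(n(n−1)) over the n called haplotypes at the site (sites with
n < 2 are skipped). Windowed θπ follows the VCFtools windowed-pi
convention: the sum of per-site π over sites in the window divided by the
full window span in bp, so monomorphic and absent positions contribute
zero. Windows are enumerated at every multiple of the step below the
chromosome length, truncated at the chromosome end; defaults are 20 kb
windows in 5 kb steps.

Tajima's D uses the standard constants a₁…e₂ for n haplotypes and
D = (π̂ − S/a₁)/√(e₁S + e₂S(S−1)). Missing-data policy: only complete-case
sites (no missing genotype within the group) enter S and π̂, so n is fixed
at twice the sample count and the variance formula remains valid. D is
undefined for S = 0 or a non-positive variance term.

The per-population summary averages, over sites variant within the
population: observed heterozygosity (fraction of heterozygous genotypes
among called individuals), unbiased expected heterozygosity
(n/(n−1))·2p(1−p) on called alleles, per-site π (the same estimator), the
per-site inbreeding coefficient Fis = 1 − obs/exp (sites with exp = 0
skipped), and the mean number of called individuals per site. These
formulas are normative for this package; column semantics follow the
per-site-averaged convention of standard population-summary tables.

LD decay uses the genotype-correlation (Rogers–Huff) r², appropriate for
unphased data: squared Pearson correlation of dosage vectors over
complete-case samples, averaged over intra-chromosome pairs in distance
bins (default 1 kb bins to 300 kb). Constant vectors and pairs with < 2
complete cases are skipped. Note the estimator has a 1/(n−1) bias floor
under linkage equilibrium.

## Differentiation

Fst is the Weir & Cockerham (1984) estimator computed from observed
genotype counts: per site the among-population component a and
within-population components b, c, with value a/(a+b+c). Sites where any
population has no called diploid, where the mean sample size is ≤ 1, or
that are monomorphic overall (denominator exactly 0) are undefined and
excluded from aggregation. Aggregation over windows or the genome is
always the weighted ratio Σa/Σ(a+b+c) — the VCFtools "weighted Fst"
convention — never a mean of per-site ratios, and negative site values
are retained unclamped. Pairwise matrices use only the two populations'
samples per cell. The 0.15 threshold used to flag strongly differentiated
pairs is a conventional rule of thumb, implemented exactly as a threshold
classification (no test).

A caveat established while testing: the estimator is unbiased for zero
differentiation only for *independently sampled* groups. Literally
duplicating one group's genotypes into a second group yields a
systematically negative value (the subtracted sampling-variance term
assumes independence), so "no differentiation" checks are formulated
distributionally (two groups drawn from one panmictic pool).

## Sweep scan

For a focal and a reference group, each window carries π(focal),
π(reference), their ratio, and the focal-vs-reference weighted Fst.
Orientation: **π-ratio = π(reference)/π(focal)**, so a sweep (diversity
loss) in the focal group gives a high ratio; this choice is configurable
at the call site by swapping the groups. Windows with π(focal) = 0 and
π(reference) > 0 get ratio +∞ and always sit in the top tail; windows
with both zero, or with no defined Fst site, are dropped.

Outliers are windows simultaneously in the upper empirical tail of Fst
and in the chosen tail(s) of the ratio. Two modes mirror the two scan
designs used in practice: group mode (focal vs pooled others, top 1% of
both statistics) and pairwise mode (focal vs one other breed, Fst top 5%
plus both 5% ratio tails, where the lower tail flags sweeps in the other
breed). Thresholds are empirical order statistics (quantile method
"higher"/"lower" so each filter keeps at most the nominal fraction), and
ties at a threshold are included; if every window ties, all are returned.
Overlapping or abutting outlier windows merge into maximal regions
(idempotent; outputs pairwise disjoint); a gene is reported for a region
when its genomic span overlaps it by ≥ 1 bp.

## Population-specific SNPs

Genotype-class frequencies (0/0, 0/1, 1/1) are computed over called
samples only; a site is ineligible for a group with zero calls. Dividing
by called rather than all samples is a deliberate divergence from the
literal "total number of samples" wording, avoiding missingness
artifacts; an all-samples mode would only deflate frequencies at
low-call sites. A class is called specific to the focal group when its
focal frequency is strictly > 0.8 and its pooled-complement frequency is
strictly < 0.2 (both inequalities strict, matching the "over"/"less
than" rule); thresholds are configurable, and raising the threshold can
only shrink the call set. The comparison group defaults to the pooled
complement (one-breed-vs-all-others design); per-population comparisons
use the same function with a different index set.

Calls are counted in non-overlapping bins anchored at coordinate 1
(default 1 Mb; bin b covers [(b−1)·10⁶+1, b·10⁶], trailing partial bin
kept). Per bin, focal and comparison counts are compared with a
**two-sided Fisher exact test** on
[[count_f, total_f − count_f], [count_o, total_o − count_o]]; bins with
p < 0.005 are flagged. The exact test was chosen (over a chi-square or
Poisson approximation) because bins are sparse; p-values match a full
rational-arithmetic hypergeometric enumeration to < 1e−10.

## Functional annotation

Location categories and precedence follow gene-based annotator defaults:
exonic (coding portion of an exon) > splice site (first/last 2 bp of an
intron; donor at the transcription-start side, strand-aware) > 5′/3′ UTR
> intronic > upstream/downstream (1 kb flanks, strand-aware) >
intergenic. Every variant receives exactly one category (highest
precedence across overlapping transcripts). Coding effects rebuild the
affected codon with the ALT allele (reverse-complemented for minus-strand
transcripts) and translate with the standard code, classifying
synonymous / nonsynonymous / stopgain / stoploss with an amino-acid
change string such as "A2D"; transcripts whose CDS length is not a
multiple of 3, or where the VCF REF disagrees with the FASTA, are flagged
"unknown" rather than guessed.

The mutation spectrum collapses each REF>ALT substitution with its
reverse complement into six classes (T:A>C:G, C:G>T:A, T:A>G:C, T:A>A:T,
C:G>A:T, C:G>G:C) and tallies genotype observations (sample × site) split
by zygosity. Indel lengths are len(ALT) − len(REF) for biallelic non-SNP
records. Percentage summaries round half-up to two decimals using exact
decimal arithmetic, so printed-precision worked examples reproduce
bit-for-bit.

## Synthetic data

The generator's purpose is controlled ground truth, not demographic
realism. Population structure is the Balding–Nichols island model: per
site an ancestral frequency p is drawn from Beta(0.5, 0.5) truncated to
[0.05, 0.95] (rejection sampling; the truncation keeps quasi-fixed sites
from dominating), and population k draws its frequency from
Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k), giving Var = F_k·p(1−p) and
realized pairwise Weir–Cockerham Fst of the order of the F parameters.
This model was chosen because its moments are analytic, enabling
parameter-recovery tests; no attempt is made to model the populations'
actual history. Genotypes are Binomial(2, p_pop) (Hardy–Weinberg within
populations) mixed with an identity-by-descent component: with
probability f (`inbreeding`, default 0.15 — inside the 0.08–0.24 Fis
range reported for real goat panels) an individual's two alleles are
copies of one draw, producing the heterozygote deficit (positive Fis)
observed in livestock data. Missingness is uniform (default 2%); REF/ALT
nucleotides are drawn with transition probability κ/(κ+1) (default κ = 2,
so transitions ≈ 2/3 of SNPs, making the two transition classes the
dominant spectrum classes as in real data).

Defaults emulate a seven-breed goat panel: populations popA…popG with
sample sizes (15, 5, 16, 16, 10, 10, 15) and per-population F spanning
0.04–0.16 so that pairwise Fst magnitudes cover the observed 0.04–0.19
range. The seed policy is one master seed from which every sub-generator
derives an independent stream by a fixed spawn key, so identical
configuration yields byte-identical VCF output and adding a stage never
perturbs another stage's draws.

**Sweep implants** rescale focal heterozygosity inside a region: the
focal allele frequency p maps to p′ with p′(1−p′) = p(1−p)/d (root
toward the focal major allele), then moves toward fixation by the
divergence boost b (default 0.8), and focal genotypes are redrawn
Binomial(2, p″) at called entries only. An identity spec (d = 1, b = 0)
returns the input object unchanged. **Specific-allele implants**
deterministically set ⌈f·n⌉ focal samples to the named class (error if
that cannot exceed the 0.8 threshold) and fill the rest with a different
class, giving exact recall targets for the classifier.

The **neutral coalescent** sampler (calibration substrate for Tajima's D)
is backed by msprime with haploid samples, population size 1 and
infinite-sites binary mutations at rate θ/2 — i.e. pairwise coalescence
rate 1 per pair and mutations Poisson(θ·branch/2), so E[π] = θ and
E[S] = θ·a₁(n). Note Tajima's D has a small negative finite-sample mean
(≈ −0.13 at n = 20, θ = 5, estimated over 2,000 replicates); calibration
checks therefore use the band |mean D| ≤ 0.3 over 200 replicates rather
than a point target.

The **toy genome** places two-exon genes (120 bp 5′UTR + 90 bp CDS /
300 bp intron / 150 bp CDS + 180 bp 3′UTR) on alternating strands with
≥ 1.1 kb clear flanks; CDS sequences are ATG + non-stop codons + TAA, so
every transcript translates cleanly start-to-stop, and models round-trip
through the GFF3 writer/reader.

### What the generator does not emulate

No linkage disequilibrium or recombination structure (sites are
independent given frequencies — LD checks can only validate the r² bias
floor, not realistic decay curves), no site-frequency-spectrum realism
beyond the Beta ancestral draw, no sequencing error, no shared drift
topology between populations (the island model cannot reproduce an
arbitrary pairwise Fst matrix, only its magnitude range), and no
selection dynamics (sweeps are implanted as endpoint patterns, not
simulated trajectories). Tests passing on this substrate validate the
estimators and the pipeline logic, not the biological interpretation of
any particular real dataset.

## Standard validation scenes (problem sizes)

- **Fst recovery**: 2 populations × 20 diploids, F = 0.10, 5,000 sites,
  no missingness, no inbreeding (clean Balding–Nichols conditions);
  recovered genome-wide weighted Fst is expected in 0.10 ± 0.02.
- **Sweep recovery**: eight 5 Mb chromosomes (40 Mb), 20+20 diploids at
  F = 0.05, ~1 SNP/500 bp, one 200 kb implant with d = 5, b = 0.8, scanned
  at 5%/5% tails. The genome is sized by a feasibility constraint:
  implant fraction (0.5%) plus the empirically measured drift-noise
  outlier coverage (~0.9–1.3% — window Fst and π-ratio are positively
  correlated under drift, so the intersection exceeds the 0.25%
  independence estimate) must stay below a 2% selected-coverage budget.
  Observed coverage is 1.3–1.9% across seeds with the implant always
  recovered as a merged region.
- **Specific-SNP closure**: 16 focal + 30 comparison samples, 40 implants
  across the three genotype classes (expected recall 100%); the
  no-signal control relabels one 60-sample panmictic panel into balanced
  30+30 groups (at this size the analytic false-call probability per site
  is ~3×10⁻⁸, so 20 relabelings of 2,000 sites are expected to yield 0
  calls — smaller groups would not make that guarantee).
- **Annotation**: 1,000 SNPs on a 40 kb toy genome with 6 genes; every
  variant must receive exactly one category and every coding-effect call
  must agree with full-CDS retranslation.

These sizes keep the whole validation suite around ten seconds of
runtime while leaving each statistic enough data to hit its stated
tolerance.

## Numerical conventions and edge cases

- Quantile thresholds use order statistics ("higher" for upper tails,
  "lower" for lower tails) with inclusive comparisons, so ties at the
  threshold are kept and each filter retains at most its nominal fraction
  plus ties.
- Undefined values propagate as NaN and are excluded from sums, means and
  quantiles; windows or sites become undefined exactly under the
  conditions listed per estimator above (never silently zeroed).
- Fisher tests with both totals zero return NaN; identical proportions
  return p = 1.
- Percentages round half-up via `decimal`, never via binary-float
  `round`.
- All randomness flows from explicit seeds; msprime seeds are mapped into
  its valid range deterministically.

## Known limitations

- Tajima's D windows with very few segregating sites are noisy and are
  reported as-is (no minimum-S filter); users should filter on the
  reported per-window S when interpreting.
- LD decay is O(pairs within max-dist) and intended for summary plots on
  moderate matrices, not biobank-scale data.
- The sweep scan's empirical-tail design means the expected number of
  selected windows is fixed by the tails, not by a null model; regions
  should be read as rankings with an implant-validated recovery property,
  not as calibrated significance calls.
- Coding-effect prediction covers single-nucleotide substitutions only;
  indels are summarized by length, and multi-nucleotide or frameshift
  effects are out of scope.
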