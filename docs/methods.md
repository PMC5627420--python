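# Methods

This note documents the models and procedures behind each pipeline stage,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that matter.

## Somatic retention model

Somatic candidates from several callers are merged on the caller-independent
key (chrom, pos, ref, alt, sample); a variant is retained when at least
`min_callers` (default 2 — "more than one program") support it. Depths are
taken from the first caller, in input order, that reports them; no
cross-caller depth reconciliation is attempted, and the full supporting set
is kept for audit. The population-frequency filter removes variants whose
known population allele frequency is *strictly* greater than
`max_pop_freq` (default 1%); an absent frequency is evidence of rarity, not
commonness, so unrecorded variants are retained. Consensus and frequency
filtering commute whenever the frequency annotation is caller-independent
(asserted as a property test), so the order in which a user applies them does
not change the result. The non-silent set is {missense, nonsense, nonstop,
splicing, frameshift_indel, inframe_indel}; unannotated variants are dropped
from burden by default (`keep_unannotated` overrides). Burden is reported as
a count and per megabase of the reference actually used.

## Mutation spectrum and signature matching

Single-base substitutions are binned by the COSMIC convention: the reference
base is collapsed to the pyrimidine strand (purine refs reverse-complement
alleles and flanks), giving 6 substitution classes × 4 × 4 flanks = 96
contexts, labels like `A[C>T]G`. A variant whose REF allele disagrees with
the reference sequence is a data-integrity error (it means the VCF and FASTA
do not belong together); a flank containing a non-ACGT base or falling off a
chromosome end is unclassifiable and counted in `n_skipped`, so
`n_snv + n_skipped` always equals the number of SNV inputs. Indels carry no
trinucleotide substitution class and are skipped with a warning.

Spectra are compared to catalog signatures by cosine similarity, the field's
default for signature attribution; ties are broken by catalog order with a
logged note. Exposures are refit by non-negative least squares over the
probability simplex: the unit-sum constraint is imposed through a heavily
weighted (1e4) penalty row appended to the catalog matrix, solved with an
exact active-set NNLS and renormalized — deterministic and accurate to
machine precision, unlike iterative simplex-projected solvers. NNLS was
preferred over a multinomial likelihood because it is deterministic,
dependency-light and standard in signature refitting.

The built-in catalog is a synthetic stand-in in COSMIC file format: a
defective-MMR-like profile with 85% of its mass on the four `N[C>T]G` bins
(the hallmark of MMR deficiency), a mild secondary C>T component, and four
decoys on well-separated supports (C>A-heavy, T>C-heavy, C>G-heavy, flat).
A real downloaded catalog loads through the same reader; signatures off
unit mass by ≤ 1e−6 are renormalized, anything worse is rejected.

## Windowed-MAF SCNA / LOH model

At a germline het site the minor-allele fraction (MAF = min(f, 1−f) of the
variant read fraction) is ≈ 0.5 in a diploid sample. Under a one-copy loss
in a tumor of purity ρ, the average copy number at the locus is 2 − ρ: the
retained allele is read at 1/(2−ρ) and the deleted allele at (1−ρ)/(2−ρ),
so the expected MAF drops from 1/2 toward (1−ρ)/(2−ρ) — 0.5 at ρ=0, ≈0.286
at ρ=0.6, 0 at ρ=1.

High-quality sites require coverage strictly above 20 in **every** sample
(the criterion is applied per sample, not on the normal alone), a dbSNP
entry, heterozygosity, and normal MAF ≥ 0.25 (boundary inclusive). Windows
are SNV-index-based — runs of `window_size` (1000) sites stepping by `step`
(500) — exactly as the windowing is defined over SNVs rather than base
pairs; the trailing partial window is dropped. The window summary is the
median, robust to the binomial tails at ~37–40× depth.

The arm-call rule has no published numeric criterion, so the decision
constants are this package's own, validated by recovery experiments: an arm
is a loss when there are at least `min_windows` windows, the median tumor
window summary is below `max_tumor_arm_maf` = 0.40, and it sits at least
`min_maf_drop` = 0.05 below the normal's median summary. Both level and drop
conditions are needed: at depth ~20 a neutral arm's median site MAF is ≈0.40
(level alone would misfire) but its tumor-normal drop is ≈0, while a real
loss at ρ ≥ 0.4 clears both comfortably. `min_windows` defaults to 2: with
1000/500 windowing, demanding three windows means ≥ 2000 surviving sites, a
threshold an arm sampled at ~2000 raw het sites can never reach once any
quality filtering removes a site, which would make every arm
`insufficient_data` under realistic site densities; two windows (≥ 1500 HQ
sites) keeps the no-curve guard while leaving the intended operating range
detectable. Arms with fewer windows than that are never called — no curve,
no call.

An LOH site is a high-quality normal-het site whose tumor MAF has collapsed
below `loh_site_max_maf` = 0.10; the count is reported per (arm, tumor)
alongside the call. LOH counting is monotone in the threshold (property
test).

## Enrichment analysis

Consequences map onto truncating {nonsense, nonstop, splicing,
frameshift_indel, inframe_indel}, missense, or other; "other" (silent,
noncoding, unknown) is excluded from the 2×2 table. Inframe indels count as
truncating because the published grouping treats indels wholesale as
truncating; the classifier keeps them as a separate vocabulary term so a
stricter analysis can re-bin them. The test is a two-sided Fisher exact
test; the odds ratio uses the Haldane–Anscombe +0.5 correction when a cell
is zero, and a chi-square p (with continuity correction) is reported
alongside since the original test behind the published p-value is unnamed.
The p-value is reported exactly as computed, never truncated to the
conventional 2.2e−16 display floor.

## Synthetic generator: what it emulates, and what it does not

The generator reproduces the *statistical* structure of a whole-genome
tumor–normal trio study at desk scale: mean depth 37× (Poisson, truncated
at ≥ 1 read), tumor purity as a free parameter (unknown for archival tumor
blocks, so never "estimated" — simulations sweep it), one-copy arm losses
only (the emulated study reports only losses; gains and copy-neutral LOH
are out of scope), hypermutated somatic SNV sets whose contexts are drawn
from a planted catalog profile and placed at reference positions that
genuinely carry the sampled trinucleotide (resampling a fresh context if
one is exhausted, so the planted spectrum is achievable by construction),
four pseudo-callers sharing true positives (each seen with probability
`caller_sensitivity` = 0.95) and adding Poisson(`private_fp_rate` = 10)
strictly private false positives, a small indel admixture (5%) solely to
exercise truncating classification, and ~10% of call keys assigned
population frequency above 1%. Consequence labels for simulated variants
are drawn from a fixed categorical distribution (45% noncoding, 25%
missense, 15% synonymous, 15% truncating classes) so that non-silent
tallies have known expectations.

All randomness flows from one root seed through named `SeedSequence`
substreams (reference, germline, somatic, callers, annotation), so a stage
can be regenerated independently — e.g. one fixed reference shared across
100 somatic seeds in the recovery experiments.

What it does **not** emulate — and therefore what passing tests do not
show about real data: read-level artifacts (mapping error, strand bias,
FFPE deamination damage), overdispersed coverage (GC waves), subclonal
structure and within-tumor heterogeneity, correlated (shared) caller false
positives, germline indels, sex chromosomes, and real centromere/telomere
geometry. Caller false positives being strictly private makes consensus
precision exactly 1 by construction; real callers share systematic
artifacts, so real-data precision is lower than these simulations suggest.

## Validation experiments and problem sizes

The recovery experiments run at the study's simulated conditions, sized to
keep the full suite in the low minutes: signature recovery uses 300 SNVs per
seed on a single shared 5 Mb reference over 100 seeds (recovered 100/100,
mean cosine ≈ 0.99); arm-loss recovery uses 3 chromosomes × 2 arms, 2000 het
sites/arm, depth 40, ρ = 0.6 over 100 seeds plus 100 fully neutral seeds
(exact recovery 100/100, zero false positives); the Fisher oracle enumerates
all 135,750 tables with total ≤ 40 (max relative error ~6e−16 against exact
integer hypergeometric enumeration); the closed-form MAF check simulates
10,000 lost-arm sites at each ρ ∈ {0.2, …, 1.0}. The closed form is checked
on the *deleted-allele* read fraction, which the ground truth identifies:
the folded MAF min(f, 1−f) is biased below (1−ρ)/(2−ρ) by binomial folding
whenever the expectation nears 0.5 (low purity), so folding-free measurement
is the correct target for the unbiased comparison; the folded version is
additionally checked at ρ = 0.6 where folding is negligible.

## Known limitations

* The arm-call thresholds were designed for ~37–40× depth and ≥ 1500 HQ
  sites per arm; shallower or sparser data will mostly return
  `insufficient_data` or miss low-purity losses (detection degrades below
  ρ ≈ 0.3 at depth 40).
* Only whole-arm events are modeled; focal events dilute the arm median and
  can be missed entirely (no segmentation is attempted).
* The minimal VCF dialect carries DP/AD/AF/CALLER only; caller-specific
  quality fields are ignored by design.
* Cosine matching attributes a spectrum to the single closest signature;
  for genuinely mixed exposures the NNLS weights, not the best match, are
  the meaningful output.
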