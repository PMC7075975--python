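# Methods

## Transmission model

Each duo consists of a mother and her child, genotyped over a panel of m
biallelic SNPs with per-allele weights w_j ≥ 0 oriented so allele 1 is the
trait-increasing (effect) allele. Genotypes g ∈ {0, 1, 2} count effect
alleles; when imputed dosages are available they are hard-called by
rounding to the nearest integer when within a threshold t of it (default
t = 0.1, round-half-up at exact midpoints), otherwise the site is missing.

Per site, the maternal transmitted allele (mt), maternal non-transmitted
allele (mnt) and paternal transmitted allele (pt) are assigned as follows:

- mother homozygous (g_m ∈ {0, 2}): mt = mnt = g_m/2 and pt = g_c − mt;
- mother heterozygous, child homozygous: mt = g_c/2, mnt = 1 − mt,
  pt = mt;
- both heterozygous (the double heterozygote): the two child haplotypes
  are each scored against the two maternal haplotypes by the count of
  matching non-missing alleles over a window of W sites centred on the
  focal variant (default W = 51, truncated at panel edges and, when the
  block structure is known, at block edges). The child haplotype whose
  best maternal match strictly exceeds the other's is maternal; its focal
  allele is mt, and mnt = pt = 1 − mt. Equal best scores are a tie and the
  site is left uncalled;
- impossible combinations (opposite homozygotes, or mother 0 with child 2
  and mother 2 with child 0) are Mendelian errors; all three components
  are missing at such sites.

The invariants mt + pt = g_c and mt + mnt = g_m hold at every called site
by construction. The window size and the count-matching rule are declared,
configurable choices; any window wholly inside a region where the child's
maternal haplotype is an exact copy of one maternal haplotype makes a
wrong call impossible (the true haplotype attains the maximal score, so an
error would require a strictly larger score — only ties can occur, and
ties are dropped).

**Tie handling.** Ties are called missing rather than broken. Breaking
ties by pushing the minor allele to the paternal side (or any
frequency-informed rule) inflates the inferred paternal minor-allele rate
because, without paternal genotypes, the paternal assignment absorbs
whatever the maternal match cannot claim. `quantify_transmission_bias`
retains that naive policy purely as a contrast: it reports, per
minor-allele frequency, the signed difference between inferred and true
minor-allele assignment rates (restricted to called sites, so a correct
caller is exactly unbiased) with Monte-Carlo standard errors over duos.
Because wide windows make ties vanishingly rare under clean phase, the
bias demonstrations use narrow windows (W = 5) where ties actually occur.

Sites where the double heterozygote cannot be examined (unphased or
haplotype-inconsistent data) are classed `tie_missing`; the call-class
vocabulary deliberately stays small.

**Duo QC.** The opposite-homozygote rate over co-called sites screens
relatedness: it is 0 for a true duo without genotype error and
2·q²·(1−q)² per site for unrelated individuals under Hardy–Weinberg
(0.125 at q = 0.5). The verdict threshold defaults to 0.01; at least 100
co-called sites are required. A per-variant missingness filter excludes
variants with a transmission-call rate below 95% across duos before
scoring.

## Scores

Raw score: Σ_j w_j · d_j over non-missing sites. Haplotype scores
(mt/pt/mnt) are multiplied by Σ_all w / Σ_called w so duos with different
missingness stay on the full-panel scale; full scores are treated the same
way. Allele-count scale: raw × m / Σw, which maps a mean dosage of one
effect allele per site to m — a full score therefore lives on
[0, 2m] (capacity 2m alleles) and a haplotype score on [0, m]. SD-units
standardize the allele-count scale by the mean and sample SD of a
designated reference group (the random subcohort), so downstream effect
sizes are per reference-SD.

Under random mating and no nurture the additivity child = mt + pt and the
independence of the four parental haplotypes give
corr(maternal, child) = 0.5, corr(half-score, its full score) = 1/√2, and
corr(mnt, child) = 0. The validation report attaches these analytic values
and flags deviations beyond 3/√n + 0.02. (Half-score-to-full-score pairs
are often loosely described as having expectation "around 0.5"; the exact
value is 1/√2 ≈ 0.707 and that is what the report uses.)

## Simulator

Haplotypes are Bernoulli(p_j) under Hardy–Weinberg with p_j ~
Uniform(0.1, 0.9) by default; weights are half-normal (scale 0.02,
floored at 1e−6 so every site is informative — the weight scale cancels
in all standardized quantities). Transmission is block-wise: within a
block of 50 consecutive sites the child copies one parental haplotype,
and the copied haplotype switches between blocks with probability 0.5
(independent blocks). This preserves local haplotype identity — the
double-heterozygote resolution step has something real to match — while
allowing recombination between blocks. No LD within blocks beyond shared
descent, no genetic map, no X chromosome, no imprinting.

Phenotypes: parental BMI z = √h2 · (own standardized full score) + noise,
h2 = 0.25 by default. Child BMI z = β_t·(mt_z + pt_z) + β_n·mnt_z +
β_e·E + residual, with the residual variance set from the analytic
decomposition 1 − (2β_t² + β_n² + β_e²) so total variance is 1 in
expectation under random mating (slightly above 1 under assortative
mating, where mt and pt correlate; an infeasible decomposition is
rejected before sampling). Defaults β_t = 0.15, β_n = β_e = 0. z-scores
map to kg/m² via location/scale constants (mothers 23.1/3.2, fathers
25.1/3.0, children at 7 years 15.6/1.6) chosen to make the simulated
magnitudes look like a Northern-European birth-cohort population.

Assortative mating pairs spouse pools by Gaussian-copula rank matching on
the parental BMI z-scores: couples are drawn from a bivariate normal with
the target correlation and each pool is rank-matched to its marginal —
exact in expectation, O(n log n), no rejection loop.

Phasing corruption follows the switch-error model: at each site, with the
configured probability, the haplotype orientation of an individual flips
from that site to the end of its block; successive events compose
(toggle), so genotypes are invariant. Missingness blanks both haplotype
alleles of an individual at a site.

All randomness derives from one seed through named substreams (panel,
haplotypes, mating, transmission, phenotypes, phase errors, missingness),
so enabling one corruption does not perturb the others' draws.

What the simulator does **not** emulate: real LD structure and imputation
uncertainty, genotyping-batch artefacts, self-report measurement error in
BMI, secular/age trends beyond a single cross-section, and non-random
cohort participation. Tests passing on synthetic cohorts therefore
establish the correctness and calibration of the algorithms under the
stated model, not the field behaviour of any particular cohort.

## Phenotype standardization and design groups

Child BMI uses LMS z-scores z = ((x/M)^L − 1)/(L·S) per sex and age-month
band (log-limit at |L| ≤ 1e−8). An external (L, M, S) reference table can
be supplied; for synthetic runs a reference is moment-matched per band
with L fixed at 1 (M = band mean, S = CV), which is transparent and exact
for the simulator's Gaussian BMI. Parental BMI uses internal z-scores.
Overweight flags are inclusive thresholds: adults at 25 kg/m², children
at a percentile-based z cutoff (default 90th percentile, z ≈ 1.28); the
childhood reference percentile is configurable because published
prevalences pin it only loosely. The maternal selection threshold for the
exposure group (default BMI ≥ 30) is deliberately a separate parameter
from the ≥ 25 overweight flag: the exposure group samples the upper tail,
not everyone flagged overweight.

Groups: REF is a uniform random sample; MO-OW a random sample of
remaining duos whose mothers meet the selection threshold; CH-OW the
remaining children with the highest BMI z (ties by duo id). Groups are
disjoint and deterministic given the seed.

## Statistical layer

OLS (for continuous child BMI in REF) and maximum-likelihood logistic
models (Newton, tolerance 1e−10, max 100 iterations) via statsmodels,
with Wald 95% CIs on the link scale, exponentiated for ORs. Separation is
an explicit `ConvergenceError` (non-convergence, or any |coefficient| >
15 on the logit scale) — never a silently huge estimate. The case-cohort
design pools REF and CH-OW with CH-OW membership as outcome, one
unadjusted model per determinant plus transmitted-GRS-adjusted
parental-BMI models. The exposure-based design pools REF and MO-OW with
child overweight as outcome and the group indicator (REF = 0) always in
the adjusted models; interaction models add group×determinant and report
per-group ORs and the interaction p-value. Ratio statistics:
effect ratio β_a/β_b and excess-OR ratio (OR_a − 1)/(OR_b − 1), both
rounded to two decimals as conventionally reported. Group descriptives
compare by Welch t-test (continuous) and pooled two-proportion z-test
(binary). No multiplicity adjustment anywhere: models are reported with
their own p-values, mirroring standard practice for these designs, and
the documentation says so rather than hiding it.

## Problem sizes used in the test suite

The validity-correlation checks use 50,000 duos × 941 variants (sampling
error on a correlation ≈ 0.004, an order below the ±0.02 check). The
oracle-equivalence check uses 500 duos × 941 variants. Parameter-recovery
uses 500 replicates of a full pipeline run — 4,000-trio source cohorts
over 250 variants, REF 500 + CH-OW 700 per replicate (matching the
~1,260-pair scale of a realistic case-cohort) — for CI coverage of the
null non-transmitted-score OR, and 100 replicates with β_n = 0.15 for the
power direction. Panel and source-cohort sizes in the replicate studies
are desk-scale choices; the statistical targets (coverage, median OR) are
invariant to them to first order.

## Known limitations

- The double-heterozygote window match uses raw match counts; no
  weighting by imputation quality or allele frequency. Rare haplotypes
  shared between spouses can in principle produce resolvable-but-wrong
  calls once phase errors are present.
- Paternal assignments inherit every maternal-side error; there is no
  independent paternal check, which is exactly why the relatedness screen
  only certifies maternity.
- The case-cohort models are plain logistic fits on the pooled groups (no
  Prentice/Barlow weighting, no sandwich SEs), appropriate for odds-of-
  selection contrasts but not for absolute-risk estimation.
- Strand-ambiguous (A/T, C/G) panel variants are matched by allele
  identity only and flagged; no frequency-based strand inference is
  attempted.
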