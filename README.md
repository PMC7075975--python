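# duogrs

Transmitted and non-transmitted parental alleles from mother–child duos:
parent-of-origin transmission inference, haplotype-resolved genetic risk
scores, and the case-cohort / exposure-based-cohort analyses that use them.

## The problem

Parental overweight predicts childhood overweight, but the phenotypic
association mixes two channels: alleles the parent actually transmitted to
the child, and everything else a parent's adiposity does to the child's
environment. When only mothers and children are genotyped, the mother's
alleles can be split, per variant, into the copy she transmitted and the
copy she did not. A weighted genetic risk score (GRS) over the
*non-transmitted* maternal alleles is then a pure probe of
environmentally mediated ("genetic nurture") maternal effects: it carries
maternal genetic information but no direct genetic pathway to the child.
The paternal transmitted alleles come for free — they are the child alleles
not assigned to the mother.

`duogrs` implements the full chain for BMI-style polygenic panels:

- **Transmission inference.** For a variant where mother or child is
  homozygous, transmission is unambiguous. At double heterozygotes the
  child haplotype whose surrounding window (default 51 sites) best matches
  a maternal haplotype — both phased upstream — is called maternally
  transmitted. Ties are left uncalled: breaking them by allele frequency
  would systematically push minor alleles onto the inferred paternal
  haplotype, a bias `quantify_transmission_bias` measures directly.
- **Scores.** Five weighted GRSs per duo (child, maternal, maternal
  transmitted, paternal transmitted, maternal non-transmitted), on the raw
  weighted-sum scale, rescaled to effect-allele counts
  (raw × n_variants / Σw, so a 941-variant panel has a per-person capacity
  of 1882 alleles for full scores, 941 for haplotype scores), and
  standardized to SD-units against a reference group.
- **Designs.** Linear models of child BMI in a random reference group
  (REF); case-cohort logistic models pooling REF with the heaviest
  children (CH-OW); exposure-based-cohort models pooling REF with
  high-BMI mothers (MO-OW), group-adjusted, with optional
  group×determinant interactions; excess-odds-ratio comparisons
  (OR−1 ratios) between genetic and phenotypic determinants.
- **Simulator.** A trio generator with Hardy–Weinberg haplotypes,
  block-wise Mendelian transmission, copula-matched assortative mating,
  polygenic phenotypes with transmitted / nurture / shared-environment
  components, switch-model phasing errors and missingness — with full
  transmission truth retained, so every inference step is testable without
  any external data.

Under random mating with no nurture effects, the score correlations have
closed forms that double as validity checks: corr(maternal, child) = 0.5,
corr(half-score, containing full score) = 1/√2 ≈ 0.707, and
corr(maternal non-transmitted, child) = 0.

## Worked example

```sh
python examples/02_infer_transmission.py
```

simulates 500 duos over 941 variants with faithful phasing and runs the
inference:

```
call classes: {'unambiguous': 378680, 'phase_resolved': 91820, 'tie_missing': 0,
               'mendel_error': 0, 'genotype_missing': 0}
maternal-transmitted accuracy vs truth: 1.0000
Mendelian errors: 0
duos passing the relatedness check: 500/500
```

About 80% of sites resolve by homozygosity alone; the remaining double
heterozygotes resolve by haplotype matching, and with clean phase every
non-tie call equals the simulator's truth. `examples/03_build_scores.py`
then builds the scores on 2,000 duos and checks their correlation
structure:

```
                             pair  observed  expected  flag
                   maternal~child  0.467840  0.500000 False
       maternal_transmitted~child  0.691871  0.707107 False
   maternal_non_transmitted~child -0.038463  0.000000 False
```

Observed correlations sit on their analytic expectations, which is the
standard validity argument for duo-derived haplotype scores. The other
examples cover cohort simulation/export (`01`), the two epidemiological
designs with ratio statistics (`04`), and the tie-policy bias demonstration
(`05`). A thin CLI (`duogrs simulate | infer-transmission | score |
analyze | validate`) wraps the same functions for shell pipelines.

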