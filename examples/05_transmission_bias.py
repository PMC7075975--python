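"""Quantify the minor-allele assignment bias of duo-based transmission.

Without paternal genotypes, how unresolved double heterozygotes are handled
matters: leaving ties uncalled is unbiased, while naively assigning the
minor allele to the paternal haplotype inflates the inferred paternal
minor-allele rate, most visibly at low minor-allele frequencies. Narrow
matching windows are used here so that ties actually occur.
"""

from duogrs.duo_phasing import quantify_transmission_bias
from duogrs.synthetic_cohort import SimParams

params = SimParams(block_length=50, seed=5)
grid = [0.05, 0.1, 0.2, 0.4]

for policy in ("missing", "paternal_minor"):
    out = quantify_transmission_bias(grid, params, n_duos=500, n_variants=300,
                                     tie_policy=policy, window=5)
    print(f"tie policy = {policy!r}")
    print(out[["maf", "bias_maternal", "bias_paternal", "se_paternal"]]
          .round(4).to_string(index=False))
    print()
# bias_* is the inferred minus true minor-allele assignment rate; positive
# bias_paternal means the paternal haplotype is over-assigned minor alleles.
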