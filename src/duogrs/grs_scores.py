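"""Weighted genetic risk scores on raw, allele-count and SD-unit scales.

A raw score is the weighted sum of effect-allele dosages over the panel,
with weights oriented so every weight is non-negative (the effect allele is
the trait-increasing one). The allele-count rescaling, raw * n_used / sum of
used weights, maps a mean dosage of one effect allele per site to
``n_variants`` — so a 941-variant panel gives per-individual counts out of a
capacity of 1882 alleles for a full (two-haplotype) score and 941 for a
haplotype (transmitted / non-transmitted) score. SD-units standardize the
allele-count scale against a designated reference group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from duogrs.io_formats import MISSING, DuoGenotypes, WeightTable
from duogrs.duo_phasing import TransmissionCalls

SCORE_COMPONENTS = (
    "child",
    "maternal",
    "maternal_transmitted",
    "paternal_transmitted",
    "maternal_non_transmitted",
)

#: alleles per site each component can carry: 2 for full scores, 1 for haplotype scores
ALLELES_PER_SITE = {
    "child": 2,
    "maternal": 2,
    "maternal_transmitted": 1,
    "paternal_transmitted": 1,
    "maternal_non_transmitted": 1,
}


def _oriented_weights(weights: WeightTable) -> np.ndarray:
    w = weights.weights
    if (w < 0).any():
        raise ValueError("weights must be oriented non-negative; call WeightTable.oriented()")
    return w


def weighted_grs(dosages, weights: WeightTable):
    """Raw weighted score: sum of w_j * dosage_j over non-missing sites.

    ``dosages`` is (n, m) or (m,) on [0, 2]; integer :data:`MISSING` or NaN
    marks missing sites. Returns (raw, n_sites_used); a row with every site
    missing is a hard error.
    """
    w = _oriented_weights(weights)
    d = np.atleast_2d(np.asarray(dosages, dtype=float))
    d[d == MISSING] = np.nan
    used = ~np.isnan(d)
    n_used = used.sum(axis=1)
    if (n_used == 0).any():
        raise ValueError("all sites missing for at least one individual")
    raw = np.nansum(d * w, axis=1)
    if np.isscalar(dosages) or np.asarray(dosages).ndim == 1:
        return float(raw[0]), int(n_used[0])
    return raw, n_used


def rescale_to_allele_counts(
    raw,
    weights: WeightTable,
    max_alleles_per_site: int = 2,
    *,
    n_used=None,
    sum_w_used=None,
):
    """Rescale a raw score to the number-of-effect-alleles scale.

    rescaled = raw * n_variants_used / sum(used weights); the result is
    interpretable as the number of effect alleles carried out of
    ``max_alleles_per_site * n_variants_used``. Defaults assume the full
    panel was used.
    """
    if max_alleles_per_site not in (1, 2):
        raise ValueError("max_alleles_per_site must be 1 or 2")
    w = _oriented_weights(weights)
    if n_used is None:
        n_used = weights.n_variants
    if sum_w_used is None:
        sum_w_used = w.sum()
    if np.any(np.asarray(sum_w_used) == 0):
        raise ValueError("sum of used weights is zero")
    return np.asarray(raw) * np.asarray(n_used) / np.asarray(sum_w_used)


def haplotype_scores(calls: TransmissionCalls, weights: WeightTable) -> pd.DataFrame:
    """Raw haplotype scores from transmission calls.

    Each component sums w_j * allele_j over its own non-missing sites and is
    multiplied by (total panel weight / called weight) so scores stay on the
    full-panel scale across duos with different missingness. A duo with zero
    called sites for any component is a hard error.
    """
    w = _oriented_weights(weights)
    total_w = w.sum()
    out = {"duo_id": calls.duo_ids}
    for name, alleles in (
        ("maternal_transmitted", calls.mt),
        ("paternal_transmitted", calls.pt),
        ("maternal_non_transmitted", calls.mnt),
    ):
        called = alleles != MISSING
        sum_w = called @ w
        if (sum_w == 0).any():
            raise ValueError(f"zero called sites for component {name}")
        raw = (np.where(called, alleles, 0) @ w) * (total_w / sum_w)
        out[f"{name}_raw"] = raw
        out[f"{name}_n_sites"] = called.sum(axis=1)
    return pd.DataFrame(out)


def build_score_set(
    duo: DuoGenotypes,
    calls: TransmissionCalls,
    weights: WeightTable,
    variant_mask: np.ndarray | None = None,
    hardcall_threshold: float = 0.1,
) -> pd.DataFrame:
    """The five scores per duo on raw and allele-count scales.

    Child and maternal full scores come from dosages when present, else
    hard genotypes; the three haplotype scores come from the transmission
    calls. ``variant_mask`` (e.g. a call-rate filter) restricts the panel
    for every score alike. SD-units are added by :func:`standardize_scores`.
    """
    from duogrs.duo_phasing import variant_call_rate_mask  # noqa: F401 (re-export context)

    if variant_mask is not None:
        keep = np.asarray(variant_mask, dtype=bool)
        weights = WeightTable(weights.df.loc[keep].reset_index(drop=True))
        duo = DuoGenotypes(
            duo_ids=duo.duo_ids, variant_ids=duo.variant_ids[keep],
            mother_h1=duo.mother_h1[:, keep], mother_h2=duo.mother_h2[:, keep],
            child_h1=duo.child_h1[:, keep], child_h2=duo.child_h2[:, keep],
            mother_phase_known=duo.mother_phase_known[:, keep],
            child_phase_known=duo.child_phase_known[:, keep],
            mother_dosage=None if duo.mother_dosage is None else duo.mother_dosage[:, keep],
            child_dosage=None if duo.child_dosage is None else duo.child_dosage[:, keep],
        )
        calls = TransmissionCalls(
            duo_ids=calls.duo_ids, variant_ids=calls.variant_ids[keep],
            mt=calls.mt[:, keep], mnt=calls.mnt[:, keep], pt=calls.pt[:, keep],
            call_class=calls.call_class[:, keep],
        )

    w = _oriented_weights(weights)
    total_w = w.sum()
    m = weights.n_variants

    def full_score(dosage, h_geno):
        d = dosage if dosage is not None else h_geno
        raw, n_used = weighted_grs(d, weights)
        used = (~np.isnan(np.where(np.asarray(d, float) == MISSING, np.nan,
                                   np.asarray(d, float))))
        sum_w_used = used @ w
        # keep full scores on the full-panel scale too, mirroring the
        # haplotype-score inflation, so counts are comparable across duos
        raw_full = raw * (total_w / sum_w_used)
        return raw_full, n_used

    child_raw, child_n = full_score(duo.child_dosage, duo.child_genotype)
    mother_raw, mother_n = full_score(duo.mother_dosage, duo.mother_genotype)

    hap = haplotype_scores(calls, weights)
    scores = pd.DataFrame({"duo_id": duo.duo_ids})
    scores["child_raw"], scores["child_n_sites"] = child_raw, child_n
    scores["maternal_raw"], scores["maternal_n_sites"] = mother_raw, mother_n
    for comp in ("maternal_transmitted", "paternal_transmitted", "maternal_non_transmitted"):
        scores[f"{comp}_raw"] = hap[f"{comp}_raw"].to_numpy()
        scores[f"{comp}_n_sites"] = hap[f"{comp}_n_sites"].to_numpy()
    for comp in SCORE_COMPONENTS:
        scores[f"{comp}_count"] = rescale_to_allele_counts(
            scores[f"{comp}_raw"].to_numpy(), weights,
            ALLELES_PER_SITE[comp], n_used=m, sum_w_used=total_w)
    scores.attrs["n_variants"] = m
    scores.attrs["allele_capacity"] = {c: ALLELES_PER_SITE[c] * m for c in SCORE_COMPONENTS}
    return scores


def standardize_scores(scores: pd.DataFrame, reference_ids) -> pd.DataFrame:
    """Add SD-unit columns, standardized against the reference duos.

    sd_units = (allele_count - mean_ref) / sd_ref per component, with mean
    and (sample) SD computed on the reference group only — the random
    reference subcohort by convention, so effects are per reference SD.
    """
    ref = scores["duo_id"].isin(np.asarray(reference_ids))
    if ref.sum() < 2:
        raise ValueError("reference subset must contain at least 2 duos")
    out = scores.copy()
    for comp in SCORE_COMPONENTS:
        col = out[f"{comp}_count"]
        mu = col[ref].mean()
        sd = col[ref].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"zero variance in reference for {comp}")
        out[f"{comp}_sd"] = (col - mu) / sd
    return out
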