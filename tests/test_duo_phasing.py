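import numpy as np
import pandas as pd
import pytest

from duogrs.duo_phasing import (
    GENOTYPE_MISSING,
    MENDEL_ERROR,
    UNAMBIGUOUS,
    _NEEDS_PHASE,
    best_guess_genotype,
    check_duo_relatedness,
    infer_duo_transmission,
    infer_site_transmission,
    quantify_transmission_bias,
    resolve_double_het,
    variant_call_rate_mask,
)
from duogrs.io_formats import MISSING, DuoGenotypes
from duogrs.synthetic_cohort import SimParams, simulate_cohort


class TestBestGuessGenotype:
    @pytest.mark.parametrize("dosage,threshold,expected", [
        (1.97, 0.1, 2),
        (1.5, 0.1, MISSING),
        (1.5, 0.5, 2),  # round-half-up tie break
        (0.04, 0.1, 0),
        (np.nan, 0.1, MISSING),
    ])
    def test_hardcall_rule(self, dosage, threshold, expected):
        assert best_guess_genotype(dosage, threshold) == expected

    def test_out_of_range_dosage_is_hard_error(self):
        with pytest.raises(ValueError, match="outside"):
            best_guess_genotype(2.3)


class TestSiteTransmission:
    @pytest.mark.parametrize("gm,gc,expected", [
        (2, 1, (1, 1, 0, UNAMBIGUOUS)),
        (2, 2, (1, 1, 1, UNAMBIGUOUS)),
        (2, 0, (MISSING, MISSING, MISSING, MENDEL_ERROR)),
        (0, 0, (0, 0, 0, UNAMBIGUOUS)),
        (0, 1, (0, 0, 1, UNAMBIGUOUS)),
        (0, 2, (MISSING, MISSING, MISSING, MENDEL_ERROR)),
        (1, 0, (0, 1, 0, UNAMBIGUOUS)),
        (1, 2, (1, 0, 1, UNAMBIGUOUS)),
        (1, 1, (MISSING, MISSING, MISSING, _NEEDS_PHASE)),
        (MISSING, 1, (MISSING, MISSING, MISSING, GENOTYPE_MISSING)),
        (2, MISSING, (MISSING, MISSING, MISSING, GENOTYPE_MISSING)),
    ])
    def test_mendelian_logic_covers_every_genotype_pair(self, gm, gc, expected):
        assert infer_site_transmission(gm, gc) == expected


class TestResolveDoubleHet:
    def test_exact_haplotype_match_decides_transmission(self):
        hap, tie = resolve_double_het(
            mother_haps=((0, 1, 0), (1, 0, 1)),
            child_haps=((0, 1, 0), (1, 1, 1)),
            focal_index=1)
        assert (hap, tie) == (1, False)

    def test_symmetric_match_is_a_tie(self):
        hap, tie = resolve_double_het(
            mother_haps=((1, 1), (1, 0)),
            child_haps=((1, 1), (1, 0)),
            focal_index=1)
        assert tie

    def test_inconsistent_window_lengths_error(self):
        with pytest.raises(ValueError, match="length"):
            resolve_double_het(((0, 1), (1, 0)), ((0, 1, 0), (1, 0, 1)), 1)


class TestInferDuoTransmission:
    def test_matches_truth_on_all_non_tie_sites(self, small_cohort, small_calls):
        calls, _ = small_calls
        called = calls.mt != MISSING
        assert np.array_equal(calls.mt[called], small_cohort.truth_mt[called])
        assert np.array_equal(calls.pt[called], small_cohort.truth_pt[called])
        assert np.array_equal(calls.mnt[called], small_cohort.truth_mnt[called])

    def test_additivity_invariants_hold_on_every_called_site(self, small_cohort, small_calls):
        calls, _ = small_calls
        ok = calls.called
        duo = small_cohort.observed
        assert np.array_equal((calls.mt + calls.pt)[ok], duo.child_genotype[ok])
        assert np.array_equal((calls.mt + calls.mnt)[ok], duo.mother_genotype[ok])

    def test_clean_duo_has_no_mendel_errors(self, small_calls):
        _, qc = small_calls
        assert qc.mendel_error_count.sum() == 0
        assert (qc.relatedness_verdict == "consistent_duo").all()

    def test_single_impossible_site_counts_one_mendel_error(self):
        duo = _duo_from_genotypes(mother=[0, 2, 1], child=[2, 2, 0])
        calls, qc = infer_duo_transmission(duo)
        assert qc.mendel_error_count.iloc[0] == 1
        assert calls.mt[0, 0] == MISSING
        assert calls.call_class[0, 0] == MENDEL_ERROR

    def test_accuracy_degrades_monotonically_with_phase_error_rate(self):
        acc = []
        for rate in (0.0, 0.01, 0.05):
            c = simulate_cohort(SimParams(
                n_trios=400, n_variants=300, phase_error_rate=rate, seed=21))
            calls, _ = infer_duo_transmission(c.observed, block_length=50)
            called = calls.mt != MISSING
            acc.append(((calls.mt == c.truth_mt) & called).sum() / called.sum())
        assert acc[0] >= acc[1] >= acc[2]
        assert acc[0] == 1.0

    def test_all_missing_duo_is_hard_error(self):
        duo = _duo_from_genotypes(mother=[MISSING, MISSING], child=[1, 1])
        with pytest.raises(ValueError, match="missing"):
            infer_duo_transmission(duo)


def _duo_from_genotypes(mother, child):
    """Unphased duo carrying the given hard genotypes (het split 0/1)."""
    gm = np.array([mother], dtype=np.int8)
    gc = np.array([child], dtype=np.int8)

    def haps(g):
        h1 = np.where(g == MISSING, MISSING, (g >= 1).astype(np.int8)).astype(np.int8)
        h2 = np.where(g == MISSING, MISSING, (g == 2).astype(np.int8)).astype(np.int8)
        return h1, h2

    mh1, mh2 = haps(gm)
    ch1, ch2 = haps(gc)
    return DuoGenotypes(
        duo_ids=np.array(["d0"]), variant_ids=np.array([f"v{i}" for i in range(gm.shape[1])]),
        mother_h1=mh1, mother_h2=mh2, child_h1=ch1, child_h2=ch2,
        mother_phase_known=np.zeros(gm.shape, bool),
        child_phase_known=np.zeros(gm.shape, bool),
    )


class TestRelatedness:
    def test_true_duos_have_zero_opposite_homozygote_rate(self, small_cohort):
        qc = check_duo_relatedness(small_cohort.observed)
        assert (qc.opposite_homozygote_rate == 0).all()
        assert (qc.relatedness_verdict == "consistent_duo").all()

    def test_unrelated_pair_rate_matches_hwe_expectation(self):
        # two unrelated individuals at MAF 0.5: P(opposite hom) = 2 * 0.25^2
        rng = np.random.default_rng(31)
        m = 2000
        h = lambda: (rng.random((1, m)) < 0.5).astype(np.int8)
        duo = DuoGenotypes(
            duo_ids=np.array(["x"]), variant_ids=np.array([f"v{i}" for i in range(m)]),
            mother_h1=h(), mother_h2=h(), child_h1=h(), child_h2=h(),
            mother_phase_known=np.ones((1, m), bool),
            child_phase_known=np.ones((1, m), bool),
        )
        qc = check_duo_relatedness(duo, rate_threshold=0.01)
        se = np.sqrt(0.125 * 0.875 / m)
        assert abs(qc.opposite_homozygote_rate.iloc[0] - 0.125) < 3 * se
        assert qc.relatedness_verdict.iloc[0] == "inconsistent"

    def test_zero_threshold_flags_single_discordant_site(self):
        duo = _duo_from_genotypes(mother=[0] * 150, child=[0] * 149 + [2])
        qc = check_duo_relatedness(duo, rate_threshold=0.0)
        assert qc.relatedness_verdict.iloc[0] == "inconsistent"

    def test_small_panel_is_rejected(self):
        duo = _duo_from_genotypes(mother=[1] * 50, child=[1] * 50)
        with pytest.raises(ValueError, match="panel"):
            check_duo_relatedness(duo)


class TestCallRateFilter:
    def test_low_call_rate_variants_are_dropped(self, small_calls):
        calls, _ = small_calls
        mask = variant_call_rate_mask(calls, min_call_rate=0.95)
        rates = calls.called.mean(axis=0)
        np.testing.assert_array_equal(mask, rates >= 0.95)


class TestTransmissionBias:
    def test_bias_table_shape_and_finite_ses(self):
        params = SimParams(n_variants=100, block_length=50, seed=41)
        out = quantify_transmission_bias([0.1, 0.3], params, n_duos=150, n_variants=100)
        assert list(out.maf) == [0.1, 0.3]
        assert np.isfinite(out[["se_maternal", "se_paternal"]]).all().all()

    def test_naive_tie_policy_creates_paternal_minor_excess(self):
        # narrow windows make double-het ties common, exposing the policy
        params = SimParams(block_length=50, seed=43)
        fair = quantify_transmission_bias([0.1], params, n_duos=400, n_variants=200,
                                          tie_policy="missing", window=5)
        naive = quantify_transmission_bias([0.1], params, n_duos=400, n_variants=200,
                                           tie_policy="paternal_minor", window=5)
        assert fair.bias_paternal.abs().iloc[0] < 1e-12
        assert naive.bias_paternal.iloc[0] > 3 * naive.se_paternal.iloc[0]
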