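"""Trio cohort simulator with known transmission truth.

Generates mother-father-child trios over a biallelic SNP panel: haplotypes
drawn under Hardy-Weinberg equilibrium, spouses paired by a Gaussian-copula
rank match to hit a target phenotypic mating correlation, children built by
block-wise Mendelian transmission, and polygenic phenotypes with
configurable transmitted, maternal-nurture and shared-environment
components. Observed duo genotypes (mother and child only, fathers
withheld) can be corrupted with switch-model phasing errors and missingness
so the downstream inference is stress-testable against the stored truth.

All randomness flows from one seed through named substreams, so toggling
one component (say, phase errors) leaves the others' draws unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from duogrs.io_formats import (
    MISSING,
    DuoGenotypes,
    WeightTable,
    write_phased_vcf,
    write_table,
)

_SUBSTREAMS = (
    "panel", "haplotypes", "mating", "transmission",
    "phenotypes", "phase_errors", "missingness",
)

# kg/m^2 location/scale used to map simulated z-scores onto plausible BMI
# magnitudes for mothers, fathers and 7-year-old children.
_BMI_SCALE = {"maternal": (23.1, 3.2), "paternal": (25.1, 3.0), "child": (15.6, 1.6)}


@dataclass
class SimParams:
    """Knobs of the trio simulator.

    ``beta_transmitted`` is the effect (per SD of score) of each transmitted
    half-score on the child BMI z-score; ``beta_nurture`` the effect of the
    maternal non-transmitted score (the genetic-nurture component, 0 under
    the null); ``spousal_corr`` the target mother-father BMI correlation;
    ``h2_parent`` the fraction of parental BMI-z variance explained by the
    parent's own full score. Transmission is block-wise: within a block of
    ``block_length`` consecutive sites the child copies one parental
    haplotype; between blocks the copied haplotype switches with probability
    ``recomb_prob`` (0.5 = independent blocks).
    """

    n_trios: int = 1000
    n_variants: int = 941
    allele_freq_law: tuple = ("uniform", 0.1, 0.9)
    weight_law: tuple = ("halfnormal", 0.02)
    beta_transmitted: float = 0.15
    beta_nurture: float = 0.0
    beta_shared_env: float = 0.0
    spousal_corr: float = 0.0
    h2_parent: float = 0.25
    block_length: int = 50
    recomb_prob: float = 0.5
    phase_error_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recomb_prob", "phase_error_rate", "genotype_missing_rate", "h2_parent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 <= self.spousal_corr <= 1.0:
            raise ValueError("spousal_corr outside [-1, 1]")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_trios < 0:
            raise ValueError("n_trios must be >= 0")
        if self.block_length < 1:
            raise ValueError("block_length must be >= 1")
        # independence-based lower bound on systematic child variance;
        # assortative mating can only add positive Mt-Pt covariance
        var_sys = 2 * self.beta_transmitted**2 + self.beta_nurture**2 + self.beta_shared_env**2
        if var_sys > 1.0:
            raise ValueError(
                f"variance components imply systematic child-BMI variance {var_sys:.3f} > 1"
            )


@dataclass
class TrioCohort:
    """Simulated trios: parental haplotypes, transmission truth, phenotypes.

    ``child_h1`` is always the maternal gamete and ``child_h2`` the paternal
    one (truth, uncorrupted). ``maternal_from_hap2[i, j]`` is True where the
    maternal gamete copied mother haplotype 2 at site j. ``observed`` holds
    the mother-child duo genotypes after phase-error/missingness corruption
    (fathers are withheld, matching a duo-only data situation).
    """

    params: SimParams
    panel: WeightTable
    allele_freqs: np.ndarray
    mother_h1: np.ndarray
    mother_h2: np.ndarray
    father_h1: np.ndarray
    father_h2: np.ndarray
    child_h1: np.ndarray
    child_h2: np.ndarray
    maternal_from_hap2: np.ndarray
    paternal_from_hap2: np.ndarray
    phenotypes: pd.DataFrame
    observed: DuoGenotypes
    truth_scores: pd.DataFrame

    @property
    def n_trios(self) -> int:
        return self.mother_h1.shape[0]

    def __len__(self) -> int:
        return self.n_trios

    @property
    def truth_mt(self) -> np.ndarray:
        """Maternal transmitted allele per site (= maternal gamete)."""
        return self.child_h1

    @property
    def truth_pt(self) -> np.ndarray:
        """Paternal transmitted allele per site (= paternal gamete)."""
        return self.child_h2

    @property
    def truth_mnt(self) -> np.ndarray:
        """Maternal non-transmitted allele per site."""
        return np.where(self.maternal_from_hap2, self.mother_h1, self.mother_h2).astype(np.int8)

    def block_ids(self) -> np.ndarray:
        return np.arange(self.params.n_variants) // self.params.block_length


def _draw_law(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    if kind == "halfnormal":
        return np.abs(rng.normal(0.0, law[1], size=size))
    if kind == "constant":
        return np.full(size, float(law[1]))
    if callable(kind):
        return np.asarray(kind(rng, size))
    raise ValueError(f"unknown distribution spec {law!r}")


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0:
        raise ValueError("degenerate score distribution (zero variance)")
    return (x - x.mean()) / sd


def _gametes(rng: np.random.Generator, h1: np.ndarray, h2: np.ndarray,
             block_length: int, recomb_prob: float) -> tuple[np.ndarray, np.ndarray]:
    """Blockwise meiosis: returns (gamete alleles, from_hap2 bool per site)."""
    n, m = h1.shape
    n_blocks = -(-m // block_length)
    first = rng.random((n, 1)) < 0.5
    if n_blocks > 1:
        switches = rng.random((n, n_blocks - 1)) < recomb_prob
        choice_blocks = np.logical_xor.accumulate(
            np.concatenate([first, switches], axis=1), axis=1)
    else:
        choice_blocks = first
    from_hap2 = np.repeat(choice_blocks, block_length, axis=1)[:, :m]
    gamete = np.where(from_hap2, h2, h1).astype(np.int8)
    return gamete, from_hap2


def _copula_pairing(rng: np.random.Generator, x_m: np.ndarray, x_f: np.ndarray,
                    target_corr: float) -> tuple[np.ndarray, np.ndarray]:
    """Permutations pairing mothers and fathers so corr(x_m, x_f) hits target.

    Draws couples from a bivariate normal with the target correlation and
    rank-matches each spouse pool to its marginal — a Gaussian copula match
    that is exact in expectation and O(n log n).
    """
    n = len(x_m)
    if n == 0:
        return np.arange(0), np.arange(0)
    if target_corr == 0.0:
        return np.arange(n), np.arange(n)
    cov = [[1.0, target_corr], [target_corr, 1.0]]
    uv = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    rank_u = np.argsort(np.argsort(uv[:, 0]))
    rank_v = np.argsort(np.argsort(uv[:, 1]))
    mothers_sorted = np.argsort(x_m, kind="stable")
    fathers_sorted = np.argsort(x_f, kind="stable")
    return mothers_sorted[rank_u], fathers_sorted[rank_v]


def simulate_cohort(params: SimParams) -> TrioCohort:
    """Simulate a trio cohort under the configured genetic architecture."""
    streams = dict(zip(
        _SUBSTREAMS,
        (np.random.default_rng(s) for s in np.random.SeedSequence(params.seed).spawn(len(_SUBSTREAMS))),
    ))
    n, m = params.n_trios, params.n_variants

    rng = streams["panel"]
    freqs = _draw_law(rng, params.allele_freq_law, m)
    weights = _draw_law(rng, params.weight_law, m)
    weights = np.maximum(weights, 1e-6)  # keep every site informative
    panel = WeightTable(pd.DataFrame({
        "variant_id": [f"var{j:05d}" for j in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "weight": weights,
    }))

    rng = streams["haplotypes"]
    draw = lambda: (rng.random((n, m)) < freqs).astype(np.int8)
    mo_h1, mo_h2, fa_h1, fa_h2 = draw(), draw(), draw(), draw()

    # parental phenotypes precede mating
    rng_ph = streams["phenotypes"]
    if n > 0:
        mo_score = (mo_h1 + mo_h2) @ weights
        fa_score = (fa_h1 + fa_h2) @ weights
        root_h2 = np.sqrt(params.h2_parent)
        noise_sd = np.sqrt(1.0 - params.h2_parent)
        z_mo = root_h2 * _standardize(mo_score) + noise_sd * rng_ph.normal(size=n)
        z_fa = root_h2 * _standardize(fa_score) + noise_sd * rng_ph.normal(size=n)
    else:
        z_mo = np.zeros(0)
        z_fa = np.zeros(0)

    mperm, fperm = _copula_pairing(streams["mating"], z_mo, z_fa, params.spousal_corr)
    mo_h1, mo_h2, z_mo = mo_h1[mperm], mo_h2[mperm], z_mo[mperm]
    fa_h1, fa_h2, z_fa = fa_h1[fperm], fa_h2[fperm], z_fa[fperm]

    rng = streams["transmission"]
    mat_gamete, mat_from2 = _gametes(rng, mo_h1, mo_h2, params.block_length, params.recomb_prob)
    pat_gamete, pat_from2 = _gametes(rng, fa_h1, fa_h2, params.block_length, params.recomb_prob)
    ch_h1, ch_h2 = mat_gamete, pat_gamete

    # truth scores on the raw (weighted-sum) scale
    mt_raw = ch_h1 @ weights
    pt_raw = ch_h2 @ weights
    mnt_raw = np.where(mat_from2, mo_h1, mo_h2) @ weights
    child_raw = mt_raw + pt_raw
    mother_raw = (mo_h1 + mo_h2) @ weights

    if n > 0:
        sys = (
            params.beta_transmitted * (_standardize(mt_raw) + _standardize(pt_raw))
            + params.beta_nurture * _standardize(mnt_raw)
            + params.beta_shared_env * rng_ph.normal(size=n)
        )
        # residual variance from the analytic decomposition (independent
        # components); unit total variance in expectation under random mating
        var_sys = (2 * params.beta_transmitted**2 + params.beta_nurture**2
                   + params.beta_shared_env**2)
        z_ch = sys + np.sqrt(1.0 - var_sys) * rng_ph.normal(size=n)
        sex = np.where(rng_ph.random(n) < 0.5, "F", "M")
        age = np.clip(np.round(rng_ph.normal(84.7, 3.0, size=n)), 78, 92).astype(int)
    else:
        z_ch = np.zeros(0)
        sex = np.zeros(0, dtype=object)
        age = np.zeros(0, dtype=int)

    duo_ids = np.array([f"duo{i:06d}" for i in range(n)])
    pheno = pd.DataFrame({
        "duo_id": duo_ids,
        "maternal_bmi": _BMI_SCALE["maternal"][0] + _BMI_SCALE["maternal"][1] * z_mo,
        "paternal_bmi": _BMI_SCALE["paternal"][0] + _BMI_SCALE["paternal"][1] * z_fa,
        "child_bmi": _BMI_SCALE["child"][0] + _BMI_SCALE["child"][1] * z_ch,
        "child_sex": sex,
        "child_age_months": age,
        "maternal_bmi_z_true": z_mo,
        "paternal_bmi_z_true": z_fa,
        "child_bmi_z_true": z_ch,
    })

    truth_scores = pd.DataFrame({
        "duo_id": duo_ids,
        "child_raw": child_raw,
        "maternal_raw": mother_raw,
        "maternal_transmitted_raw": mt_raw,
        "paternal_transmitted_raw": pt_raw,
        "maternal_non_transmitted_raw": mnt_raw,
    })

    observed = DuoGenotypes(
        duo_ids=duo_ids,
        variant_ids=panel.variant_ids.copy(),
        mother_h1=mo_h1.copy(), mother_h2=mo_h2.copy(),
        child_h1=ch_h1.copy(), child_h2=ch_h2.copy(),
        mother_phase_known=np.ones((n, m), dtype=bool),
        child_phase_known=np.ones((n, m), dtype=bool),
    )
    if params.phase_error_rate > 0:
        observed = inject_phase_errors(
            observed, params.phase_error_rate,
            rng=streams["phase_errors"], block_length=params.block_length)
    if params.genotype_missing_rate > 0:
        rng = streams["missingness"]
        for who in ("mother", "child"):
            miss = rng.random((n, m)) < params.genotype_missing_rate
            for hap in ("h1", "h2"):
                arr = getattr(observed, f"{who}_{hap}")
                arr[miss] = MISSING

    return TrioCohort(
        params=params, panel=panel, allele_freqs=freqs,
        mother_h1=mo_h1, mother_h2=mo_h2, father_h1=fa_h1, father_h2=fa_h2,
        child_h1=ch_h1, child_h2=ch_h2,
        maternal_from_hap2=mat_from2, paternal_from_hap2=pat_from2,
        phenotypes=pheno, observed=observed, truth_scores=truth_scores,
    )


def inject_phase_errors(
    duo: DuoGenotypes,
    rate: float,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    block_length: int | None = None,
) -> DuoGenotypes:
    """Apply independent switch errors to mother and child haplotypes.

    At each site, with probability ``rate``, the haplotype orientation flips
    from that site to the end of its block (successive switch events
    compose, i.e. toggle). Genotypes are unchanged by construction; with
    rate 0 the object is returned verbatim.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate outside [0, 1]")
    if rate == 0.0:
        return duo
    if rng is None:
        rng = np.random.default_rng(seed)
    n, m = duo.mother_h1.shape
    block = (np.arange(m) // block_length) if block_length else np.zeros(m, dtype=int)

    def _switched(h1: np.ndarray, h2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        events = rng.random((n, m)) < rate
        cum = np.cumsum(events, axis=1)
        # restart the parity at each block boundary
        starts = np.flatnonzero(np.diff(block, prepend=block[0] - 1))
        offset = np.zeros((n, m), dtype=cum.dtype)
        for s in starts[1:]:
            offset[:, s:] = cum[:, s - 1:s]
        swapped = ((cum - offset) % 2).astype(bool)
        return (np.where(swapped, h2, h1).astype(np.int8),
                np.where(swapped, h1, h2).astype(np.int8))

    mo1, mo2 = _switched(duo.mother_h1, duo.mother_h2)
    ch1, ch2 = _switched(duo.child_h1, duo.child_h2)
    return replace(duo, mother_h1=mo1, mother_h2=mo2, child_h1=ch1, child_h2=ch2)


def export_cohort(cohort: TrioCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the observed duos (VCF), panel, phenotypes, duo list and truth.

    Fathers never appear in the VCF sample list — the exported data mirror a
    mother-child duo study. Returns the written paths by name.
    """
    if cohort.n_trios == 0:
        raise ValueError("refusing to export an empty cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs = cohort.observed
    n = cohort.n_trios
    mother_ids = [f"M{i:06d}" for i in range(n)]
    child_ids = [f"C{i:06d}" for i in range(n)]

    paths = {
        "vcf": out / "duos.vcf",
        "weights": out / "weights.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "duos": out / "duos.tsv",
        "truth": out / "truth.tsv",
    }
    write_phased_vcf(
        paths["vcf"], cohort.panel,
        mother_ids + child_ids,
        np.vstack([obs.mother_h1, obs.child_h1]),
        np.vstack([obs.mother_h2, obs.child_h2]),
        np.vstack([obs.mother_phase_known, obs.child_phase_known]),
    )
    cohort.panel.to_tsv(paths["weights"])
    write_table(
        cohort.phenotypes.drop(
            columns=[c for c in cohort.phenotypes.columns if c.endswith("_true")]),
        paths["phenotypes"], precision=8)
    write_table(pd.DataFrame({"mother_id": mother_ids, "child_id": child_ids}),
                paths["duos"])
    write_table(cohort.truth_scores, paths["truth"], precision=10)
    return paths
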