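"""Readers and writers for the formats the pipeline touches.

Variant weight panels and phenotypes travel as TSV; genotypes as phased
VCF 4.x (read through cyvcf2, written by a small text formatter since the
output carries a single GT FORMAT field). Alleles are recoded internally so
that ``1`` always denotes the effect (trait-increasing) allele of the panel.
Positions are 1-based throughout, matching VCF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing haplotype allele / genotype
MISSING = -1

_WEIGHT_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "weight"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Raised when an input file violates its contract."""


# ---------------------------------------------------------------------------
# Weight table
# ---------------------------------------------------------------------------

@dataclass
class WeightTable:
    """A variant panel: per-variant effect allele and per-allele weight.

    Rows are kept in file order; ``variant_id`` values are unique and each
    row's two alleles differ. Weights are per-allele effect sizes on the
    discovery trait.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _WEIGHT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"weight table missing columns: {missing}")
        self.df = self.df[_WEIGHT_COLUMNS].reset_index(drop=True)
        dup = self.df["variant_id"][self.df["variant_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate variant_id: {dup.iloc[0]!r}")
        w = pd.to_numeric(self.df["weight"], errors="coerce")
        if w.isna().any() or not np.isfinite(w).all():
            bad = self.df.loc[~np.isfinite(w.fillna(np.nan)), "variant_id"]
            raise FormatError(f"non-numeric or non-finite weight for {bad.iloc[0]!r}")
        self.df["weight"] = w.astype(float)
        same = self.df["effect_allele"] == self.df["other_allele"]
        if same.any():
            raise FormatError(
                f"identical alleles for {self.df.loc[same, 'variant_id'].iloc[0]!r}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_variants(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.df["weight"].to_numpy()

    def allele_capacity(self, max_alleles_per_site: int = 2) -> int:
        """Total number of effect/other alleles an individual carries."""
        return max_alleles_per_site * self.n_variants

    def oriented(self) -> "WeightTable":
        """Return a copy with every weight non-negative.

        Rows with a negative weight have (effect, other) alleles swapped and
        the weight sign flipped, so the effect allele is always the
        trait-increasing one. Applying twice is a no-op.
        """
        df = self.df.copy()
        neg = df["weight"] < 0
        eff = df.loc[neg, "effect_allele"].copy()
        df.loc[neg, "effect_allele"] = df.loc[neg, "other_allele"]
        df.loc[neg, "other_allele"] = eff
        df.loc[neg, "weight"] = -df.loc[neg, "weight"]
        return WeightTable(df)

    def is_strand_ambiguous(self) -> np.ndarray:
        """A/T and C/G variants, unmatchable across strand flips."""
        eff = self.df["effect_allele"].map(_COMPLEMENT)
        return (eff == self.df["other_allele"]).to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        write_table(self.df, path)


def read_weights(path: str | Path) -> WeightTable:
    """Read a variant-weight TSV (columns of :data:`_WEIGHT_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})
    table = WeightTable(df)
    amb = table.is_strand_ambiguous()
    if amb.any():
        logger.warning(
            "%d strand-ambiguous (A/T or C/G) panel variants; matched by allele identity only",
            int(amb.sum()),
        )
    return table


# ---------------------------------------------------------------------------
# Duo genotypes
# ---------------------------------------------------------------------------

@dataclass
class DuoGenotypes:
    """Phased haplotypes for a collection of mother-child duos over a panel.

    All allele arrays are ``int8`` of shape ``(n_duos, n_variants)`` with
    alleles coded ``1`` = effect allele, ``0`` = other allele and
    :data:`MISSING` for no call. ``phase_known`` marks sites whose two
    haplotype alleles came from a phased ("|") genotype. Dosages, when
    present, live on ``[0, 2]`` with NaN for missing.
    """

    duo_ids: np.ndarray
    variant_ids: np.ndarray
    mother_h1: np.ndarray
    mother_h2: np.ndarray
    child_h1: np.ndarray
    child_h2: np.ndarray
    mother_phase_known: np.ndarray
    child_phase_known: np.ndarray
    mother_dosage: np.ndarray | None = None
    child_dosage: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, m = self.mother_h1.shape
        for name in ("mother_h2", "child_h1", "child_h2",
                     "mother_phase_known", "child_phase_known"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(f"{name} shape {arr.shape} != {(n, m)}")

    @property
    def n_duos(self) -> int:
        return self.mother_h1.shape[0]

    @property
    def n_variants(self) -> int:
        return self.mother_h1.shape[1]

    def __len__(self) -> int:
        return self.n_duos

    @staticmethod
    def _genotype(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        g = (h1 + h2).astype(np.int8)
        g[(h1 == MISSING) | (h2 == MISSING)] = MISSING
        return g

    @property
    def mother_genotype(self) -> np.ndarray:
        return self._genotype(self.mother_h1, self.mother_h2)

    @property
    def child_genotype(self) -> np.ndarray:
        return self._genotype(self.child_h1, self.child_h2)

    def subset(self, rows: np.ndarray) -> "DuoGenotypes":
        return DuoGenotypes(
            duo_ids=self.duo_ids[rows],
            variant_ids=self.variant_ids,
            mother_h1=self.mother_h1[rows],
            mother_h2=self.mother_h2[rows],
            child_h1=self.child_h1[rows],
            child_h2=self.child_h2[rows],
            mother_phase_known=self.mother_phase_known[rows],
            child_phase_known=self.child_phase_known[rows],
            mother_dosage=None if self.mother_dosage is None else self.mother_dosage[rows],
            child_dosage=None if self.child_dosage is None else self.child_dosage[rows],
        )


def read_phased_vcf(
    path: str | Path,
    panel: WeightTable,
    mother_ids: Sequence[str],
    child_ids: Sequence[str],
) -> DuoGenotypes:
    """Read phased duo genotypes from a VCF, restricted to the panel.

    Alleles are recoded so 1 = panel effect allele. Sites whose REF/ALT pair
    does not match the panel alleles (in either orientation) are dropped with
    a warning; multiallelic records are dropped; panel variants absent from
    the VCF stay missing for every duo. Unphased ("/") genotypes keep their
    alleles but set ``phase_known`` to False.
    """
    from cyvcf2 import VCF

    if len(mother_ids) != len(child_ids):
        raise ValueError("mother_ids and child_ids must pair up")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    for sid in list(mother_ids) + list(child_ids):
        if sid not in sample_idx:
            raise FormatError(f"sample {sid!r} not present in VCF {path}")

    site_index = {
        (str(c), int(p)): j
        for j, (c, p) in enumerate(zip(panel.df["chrom"], panel.df["pos"]))
    }
    eff = panel.df["effect_allele"].to_numpy()
    oth = panel.df["other_allele"].to_numpy()

    nsamp = len(samples)
    m = panel.n_variants
    h1 = np.full((nsamp, m), MISSING, dtype=np.int8)
    h2 = np.full((nsamp, m), MISSING, dtype=np.int8)
    phased = np.zeros((nsamp, m), dtype=bool)
    dosage = np.full((nsamp, m), np.nan)
    any_ds = False

    for v in vcf:
        key = (str(v.CHROM), int(v.POS))
        j = site_index.get(key)
        if j is None:
            continue
        if len(v.ALT) != 1:
            logger.warning("dropping multiallelic record at %s:%d", *key)
            continue
        ref, alt = v.REF, v.ALT[0]
        if {ref, alt} != {eff[j], oth[j]}:
            logger.warning(
                "alleles %s/%s at %s:%d do not match panel %s/%s; variant dropped",
                ref, alt, key[0], key[1], eff[j], oth[j],
            )
            continue
        # code 1 = effect allele: identity map if ALT is the effect allele
        flip = alt != eff[j]
        gts = np.asarray(v.genotypes, dtype=object)
        a0 = np.array([g[0] for g in gts], dtype=np.int8)
        a1 = np.array([g[1] for g in gts], dtype=np.int8)
        ph = np.array([bool(g[2]) for g in gts])
        if flip:
            a0 = np.where(a0 >= 0, 1 - a0, MISSING).astype(np.int8)
            a1 = np.where(a1 >= 0, 1 - a1, MISSING).astype(np.int8)
        else:
            a0 = np.where(a0 >= 0, a0, MISSING).astype(np.int8)
            a1 = np.where(a1 >= 0, a1, MISSING).astype(np.int8)
        h1[:, j] = a0
        h2[:, j] = a1
        phased[:, j] = ph & (a0 != MISSING) & (a1 != MISSING)
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            any_ds = True
            d = np.asarray(ds, dtype=float).reshape(-1)
            dosage[:, j] = 2.0 - d if flip else d

    mi = np.array([sample_idx[s] for s in mother_ids])
    ci = np.array([sample_idx[s] for s in child_ids])
    return DuoGenotypes(
        duo_ids=np.array([f"{mo}:{ch}" for mo, ch in zip(mother_ids, child_ids)]),
        variant_ids=panel.variant_ids.copy(),
        mother_h1=h1[mi], mother_h2=h2[mi],
        child_h1=h1[ci], child_h2=h2[ci],
        mother_phase_known=phased[mi], child_phase_known=phased[ci],
        mother_dosage=dosage[mi] if any_ds else None,
        child_dosage=dosage[ci] if any_ds else None,
    )


def write_phased_vcf(
    path: str | Path,
    panel: WeightTable,
    sample_ids: Sequence[str],
    hap1: np.ndarray,
    hap2: np.ndarray,
    phase_known: np.ndarray | None = None,
) -> None:
    """Write panel sites as a minimal phased VCF (GT only, uncompressed).

    ``hap1``/``hap2`` are (n_samples, n_variants) effect-allele codes; the
    effect allele is written as ALT so the on-disk 0/1 coding matches the
    internal one.
    """
    n, m = hap1.shape
    if len(sample_ids) != n:
        raise ValueError("sample_ids length mismatch")
    df = panel.df
    sep = np.where(phase_known, "|", "/") if phase_known is not None else np.full((n, m), "|")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(df["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        a1 = np.where(hap1 == MISSING, ".", hap1.astype(str))
        a2 = np.where(hap2 == MISSING, ".", hap2.astype(str))
        for j in range(m):
            row = df.iloc[j]
            gts = np.char.add(np.char.add(a1[:, j], sep[:, j]), a2[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.other_allele}\t"
                f"{row.effect_allele}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

_PHENO_MANDATORY = ["duo_id", "maternal_bmi", "child_bmi", "child_sex", "child_age_months"]


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype TSV: one row per duo.

    Mandatory columns: duo_id, maternal_bmi, child_bmi, child_sex,
    child_age_months; paternal_bmi is optional per row (the study's paternal
    analyses have smaller N). Rows with a non-positive BMI are rejected with
    a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"duo_id": str, "child_sex": str})
    missing = [c for c in _PHENO_MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"phenotype table missing mandatory columns: {missing}")
    if "paternal_bmi" not in df.columns:
        df["paternal_bmi"] = np.nan
    for col in ("maternal_bmi", "paternal_bmi", "child_bmi"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = (df["maternal_bmi"] <= 0) | (df["child_bmi"] <= 0) | (df["paternal_bmi"] <= 0)
    bad = bad.fillna(False)
    if bad.any():
        logger.warning("rejecting %d phenotype rows with non-positive BMI", int(bad.sum()))
        df = df[~bad]
    if not df["child_sex"].isin(["F", "M"]).all():
        raise FormatError("child_sex must be F or M")
    df["child_age_months"] = df["child_age_months"].astype(int)
    return df.reset_index(drop=True)


def write_table(records: pd.DataFrame, path: str | Path, *,
                allow_empty: bool = False, precision: int = 6) -> None:
    """Write a result table as TSV with a fixed column order.

    Floats are rendered with ``precision`` significant digits; an empty
    frame is only written when ``allow_empty`` is set.
    """
    if len(records) == 0 and not allow_empty:
        raise ValueError("refusing to write empty table without allow_empty=True")
    records.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}g")
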