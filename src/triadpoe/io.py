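"""Reading and writing PLINK 1 binary genotype data and assembling case-parent triads.

Genotypes are coded as the number of copies of allele2 (the .bim A2 column):
0, 1, 2, or :data:`MISSING` (-1). The .bed file is SNP-major: for each SNP,
samples are packed 4 per byte, 2 bits each, with PLINK 1's encoding

=====  ==========================
bits   meaning
=====  ==========================
00     homozygous allele1 (code 0)
01     missing
10     heterozygous (code 1)
11     homozygous allele2 (code 2)
=====  ==========================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeDataset",
    "Triad",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "read_covariates",
    "assemble_triads",
]

logger = logging.getLogger(__name__)

MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit PLINK code -> allele2 dosage (MISSING for the 01 pattern)
_DECODE = np.array([0, MISSING, 1, 2], dtype=np.int8)

OBESITY_BMI_CUT = 28.0  # kg/m^2


class PlinkFormatError(ValueError):
    """Raised for malformed .bed/.bim/.fam files."""


@dataclass
class GenotypeDataset:
    """In-memory biallelic genotype matrix with sample pedigree and SNP metadata.

    Attributes
    ----------
    samples : pandas.DataFrame
        Columns ``fid, iid, father, mother, sex, affection`` (fam conventions:
        affection 2 = affected, 1 = unaffected, -9/0 = unknown).
    snps : pandas.DataFrame
        Columns ``rsid, chrom, pos, allele1, allele2``; positions 1-based.
    genotypes : numpy.ndarray
        ``(n_samples, n_snps)`` int8 matrix of allele2 dosages, -1 = missing.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.genotypes.shape
        if n != len(self.samples) or m != len(self.snps):
            raise ValueError(
                f"genotype matrix {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,-1}")
        if self.snps["rsid"].duplicated().any():
            dups = self.snps.loc[self.snps["rsid"].duplicated(), "rsid"].tolist()
            raise ValueError(f"duplicate rsids: {dups[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_index(self) -> pd.Series:
        """Map iid -> row number; raises on duplicate individual ids."""
        iid = self.samples["iid"]
        if iid.duplicated().any():
            raise ValueError(f"duplicate individual ids: {iid[iid.duplicated()].tolist()[:5]}")
        return pd.Series(np.arange(len(iid)), index=iid)

    def subset(self, sample_rows=None, snp_cols=None) -> "GenotypeDataset":
        sr = np.arange(self.n_samples) if sample_rows is None else np.asarray(sample_rows)
        sc = np.arange(self.n_snps) if snp_cols is None else np.asarray(snp_cols)
        return GenotypeDataset(
            samples=self.samples.iloc[sr].reset_index(drop=True),
            snps=self.snps.iloc[sc].reset_index(drop=True),
            genotypes=self.genotypes[np.ix_(sr, sc)].copy(),
        )


@dataclass
class Triad:
    """One mother/father/affected-child genotype trio with child covariates.

    Genotypes are views into the parent dataset; ``genotypes(j)`` returns the
    ``(g_M, g_F, g_C)`` triple at SNP column ``j``.
    """

    child_id: str
    mother_id: str
    father_id: str
    mother_row: int
    father_row: int
    child_row: int
    dataset: GenotypeDataset = field(repr=False)
    affected: bool = True
    sex: str | None = None          # "male" / "female" / None
    smoking: int | None = None      # 0/1
    drinking: int | None = None     # 0/1
    bmi: float | None = None        # kg/m^2
    covariates_missing: bool = False

    @property
    def bmi_class(self) -> str | None:
        """Obesity class at the 28 kg/m^2 cut: '>=28' or '<28'."""
        if self.bmi is None or np.isnan(self.bmi):
            return None
        return ">=28" if self.bmi >= OBESITY_BMI_CUT else "<28"

    def genotypes(self, snp_col: int) -> tuple[int, int, int]:
        g = self.dataset.genotypes
        return (
            int(g[self.mother_row, snp_col]),
            int(g[self.father_row, snp_col]),
            int(g[self.child_row, snp_col]),
        )

    def stratum_value(self, variable: str) -> str | None:
        """Offspring covariate level for stratification (None = missing)."""
        if variable == "smoking":
            return None if self.smoking is None else ("yes" if self.smoking else "no")
        if variable == "drinking":
            return None if self.drinking is None else ("yes" if self.drinking else "no")
        if variable == "bmi_class":
            return self.bmi_class
        if variable == "sex":
            return self.sex
        raise ValueError(f"unknown stratum variable {variable!r}")


def read_plink(prefix_or_bed, bim_path=None, fam_path=None) -> GenotypeDataset:
    """Read a PLINK 1 binary fileset.

    Accepts either a common path prefix or explicit ``(bed, bim, fam)`` paths.
    """
    if bim_path is None and fam_path is None:
        prefix = str(prefix_or_bed)
        if prefix.endswith(".bed"):
            prefix = prefix[:-4]
        bed_path = prefix + ".bed"
        bim_path = prefix + ".bim"
        fam_path = prefix + ".fam"
    else:
        bed_path = str(prefix_or_bed)

    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None, dtype=str,
        names=["fid", "iid", "father", "mother", "sex", "affection"],
    )
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "rsid", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "rsid": str, "allele1": str, "allele2": str},
    )
    snps = bim[["rsid", "chrom", "pos", "allele1", "allele2"]].copy()

    n_samples, n_snps = len(fam), len(snps)
    raw = Path(bed_path).read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes (not a PLINK 1 .bed file)")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: mode byte {raw[2]:#04x} is not SNP-major (0x01)")
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + bytes_per_snp * n_snps
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{bed_path}: {len(raw)} bytes, expected {expected} "
            f"for {n_samples} samples x {n_snps} SNPs (truncated or corrupt)"
        )

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snps, bytes_per_snp)
    # unpack 2-bit fields, low bits first within each byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes2bit = (data[:, :, None] >> shifts) & 0b11          # (n_snps, bytes, 4)
    codes2bit = codes2bit.reshape(n_snps, -1)[:, :n_samples]
    genotypes = _DECODE[codes2bit].T.copy()                   # (n_samples, n_snps)

    return GenotypeDataset(samples=fam, snps=snps, genotypes=genotypes)


def write_plink(dataset: GenotypeDataset, prefix) -> None:
    """Write the dataset as .bed/.bim/.fam (SNP-major PLINK 1 binary)."""
    prefix = str(prefix)
    dataset.samples.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame({
        "chrom": dataset.snps["chrom"],
        "rsid": dataset.snps["rsid"],
        "cm": 0,
        "pos": dataset.snps["pos"],
        "allele1": dataset.snps["allele1"],
        "allele2": dataset.snps["allele2"],
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)

    n_samples, n_snps = dataset.genotypes.shape
    g = dataset.genotypes
    two_bit = np.empty_like(g, dtype=np.uint8)
    two_bit[g == 0] = 0b00
    two_bit[g == 1] = 0b10
    two_bit[g == 2] = 0b11
    two_bit[g == MISSING] = 0b01

    bytes_per_snp = (n_samples + 3) // 4
    padded = np.full((n_snps, bytes_per_snp * 4), 0b00, dtype=np.uint8)
    padded[:, :n_samples] = two_bit.T
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(n_snps, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())


def read_covariates(path) -> pd.DataFrame:
    """Read the offspring covariate TSV.

    Expected header: ``individual_id, affected, smoking, drinking, bmi``
    (affected/smoking/drinking coded 0/1, bmi numeric kg/m^2). Extra columns
    (e.g. ``sex``) are carried through.
    """
    cov = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    required = {"individual_id", "affected", "smoking", "drinking", "bmi"}
    missing = required - set(cov.columns)
    if missing:
        raise ValueError(f"covariate file {path} lacks columns {sorted(missing)}")
    if cov["individual_id"].duplicated().any():
        raise ValueError("duplicate individual_id in covariate file")
    return cov


def assemble_triads(dataset: GenotypeDataset, covariates: pd.DataFrame | None = None) -> list[Triad]:
    """Assemble one triad per affected offspring with both parents genotyped.

    A family with k affected offspring yields k triads sharing the same parent
    rows. Offspring lacking either parent in the dataset are excluded (logged).
    Offspring without a covariate row keep their triad but are flagged, which
    excludes them from stratified fits only.
    """
    idx = dataset.sample_index()
    cov_by_id: dict[str, pd.Series] = {}
    if covariates is not None:
        if covariates["individual_id"].duplicated().any():
            raise ValueError("duplicate individual_id in covariates")
        cov_by_id = {r["individual_id"]: r for _, r in covariates.iterrows()}

    triads: list[Triad] = []
    n_excluded = 0
    for _, row in dataset.samples.iterrows():
        affected = str(row["affection"]) == "2"
        if not affected:
            continue
        mother, father = row["mother"], row["father"]
        if mother in ("0", "") or father in ("0", "") or mother not in idx.index or father not in idx.index:
            n_excluded += 1
            logger.info("offspring %s excluded: parent(s) not genotyped", row["iid"])
            continue
        if mother == father:
            raise ValueError(f"offspring {row['iid']}: mother and father ids are identical")
        cov = cov_by_id.get(row["iid"])
        sex = None
        if str(row["sex"]) in ("1", "2"):
            sex = "male" if str(row["sex"]) == "1" else "female"
        triad = Triad(
            child_id=row["iid"],
            mother_id=mother,
            father_id=father,
            mother_row=int(idx[mother]),
            father_row=int(idx[father]),
            child_row=int(idx[row["iid"]]),
            dataset=dataset,
            affected=True,
            sex=sex,
            covariates_missing=cov is None and covariates is not None,
        )
        if cov is not None:
            def _int_or_none(v):
                return None if pd.isna(v) else int(v)
            triad.smoking = _int_or_none(cov.get("smoking"))
            triad.drinking = _int_or_none(cov.get("drinking"))
            bmi = cov.get("bmi")
            triad.bmi = None if pd.isna(bmi) else float(bmi)
            if "sex" in cov.index and not pd.isna(cov["sex"]):
                triad.sex = str(cov["sex"])
        triads.append(triad)
    if n_excluded:
        logger.info("assemble_triads: %d affected offspring excluded (incomplete trio)", n_excluded)
    return triads


def participant_roster(triads: list[Triad]) -> set[str]:
    """Distinct individuals appearing in any triad (parents shared across
    sibling triads counted once)."""
    roster: set[str] = set()
    for t in triads:
        roster.update((t.child_id, t.mother_id, t.father_id))
    return roster
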