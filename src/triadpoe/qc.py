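"""Per-sample and per-SNP quality control for case-parent triad genotype data.

Filters and defaults follow standard array-QC practice for family data:
call rate >= 95% (samples and SNPs), Hardy-Weinberg exact P > 1e-6 on
founders, MAF > 1%, Mendelian error rate < 10% per SNP and < 5% per sample,
and founder heterozygosity within 3 SD of the founder mean. Samples are
filtered first (together with their triads); SNP statistics are then computed
on the surviving samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeDataset, Triad

__all__ = [
    "QCThresholds",
    "QCReport",
    "snp_summary",
    "hwe_exact_test",
    "mendel_check",
    "apply_qc",
]


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; the defaults are the standard array-QC values."""

    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    snp_mendel_error_max: float = 0.10
    sample_mendel_error_max: float = 0.05
    het_sd_window: float = 3.0

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "snp_call_rate_min", "hwe_p_min",
                     "maf_min", "snp_mendel_error_max", "sample_mendel_error_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.het_sd_window <= 0:
            raise ValueError("het_sd_window must be positive")


@dataclass
class QCReport:
    """Per-SNP and per-sample statistics with pass flags and failure reasons.

    ``filter_order`` records the sequence the filters were applied in, so the
    flags are reproducible from the stored statistics and thresholds.
    """

    snp_table: pd.DataFrame
    sample_table: pd.DataFrame
    thresholds: QCThresholds
    filter_order: list[str] = field(default_factory=lambda: [
        "sample_call_rate", "sample_het", "sample_mendel",
        "snp_call_rate", "snp_maf", "snp_hwe", "snp_mendel",
    ])

    def write(self, snp_path, sample_path) -> None:
        self.snp_table.to_csv(snp_path, sep="\t", index=False)
        self.sample_table.to_csv(sample_path, sep="\t", index=False)


def snp_summary(dataset: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP call rate and minor allele frequency.

    MAF is ``min(f, 1-f)`` with ``f`` the allele2 frequency among non-missing
    genotypes; NaN for all-missing SNPs (which then fail QC).
    """
    g = dataset.genotypes
    obs = g != MISSING
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / g.shape[0]
    dose = np.where(obs, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_obs > 0, dose / (2.0 * n_obs), np.nan)
    maf = np.minimum(f, 1.0 - f)
    return pd.DataFrame({
        "rsid": dataset.snps["rsid"].to_numpy(),
        "call_rate": call_rate,
        "freq_allele2": f,
        "maf": maf,
    })


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts (same parity) whose conditional probability does not
    exceed that of the observed configuration. Returns a p-value in (0, 1].
    """
    for v in (n_hom1, n_het, n_hom2):
        if v < 0 or int(v) != v:
            raise ValueError("genotype counts must be nonnegative integers")
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("no data: all genotype counts are zero")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het  # rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # P(het = h | allele counts) ∝ n! / (h1! h! h2!) * 2^h  with
    # h1 = (n_rare - h)/2 rare homs, h2 = n - h1 - h common homs
    h1 = (n_rare - hets) // 2
    h2 = n - h1 - hets
    valid = h2 >= 0
    hets, h1, h2 = hets[valid], h1[valid], h2[valid]
    logp = (hets * np.log(2.0)
            - gammaln(h1 + 1) - gammaln(hets + 1) - gammaln(h2 + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    # tolerance guards against ties lost to floating point
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


_MENDEL_OK = np.zeros((3, 3, 3), dtype=bool)
for _m in range(3):
    for _f in range(3):
        _m_alleles = {0: (0,), 1: (0, 1), 2: (1,)}[_m]
        _f_alleles = {0: (0,), 1: (0, 1), 2: (1,)}[_f]
        for _cm in _m_alleles:
            for _cf in _f_alleles:
                _MENDEL_OK[_m, _f, _cm + _cf] = True


def mendel_check(g_m: int, g_f: int, g_c: int) -> bool:
    """True iff the child genotype is producible from one allele of each parent.

    Any missing member makes the trio uncountable and returns True.
    """
    if MISSING in (g_m, g_f, g_c):
        return True
    return bool(_MENDEL_OK[g_m, g_f, g_c])


def _mendel_consistent_matrix(dataset: GenotypeDataset, triads: list[Triad]) -> np.ndarray:
    """(n_triads, n_snps) boolean matrix; True where the trio is countable and
    consistent OR uncountable (missing member)."""
    g = dataset.genotypes
    out = np.ones((len(triads), dataset.n_snps), dtype=bool)
    for i, t in enumerate(triads):
        gm, gf, gc = g[t.mother_row], g[t.father_row], g[t.child_row]
        countable = (gm != MISSING) & (gf != MISSING) & (gc != MISSING)
        idx = np.where(countable)[0]
        out[i, idx] = _MENDEL_OK[gm[idx], gf[idx], gc[idx]]
    return out


def _founder_mask(dataset: GenotypeDataset, triads: list[Triad]) -> np.ndarray:
    """Samples that appear as a parent in some triad (and not as a child)."""
    parents = {t.mother_row for t in triads} | {t.father_row for t in triads}
    children = {t.child_row for t in triads}
    mask = np.zeros(dataset.n_samples, dtype=bool)
    mask[sorted(parents - children)] = True
    if not mask.any():  # no pedigree structure: treat everyone as a founder
        mask[:] = True
    return mask


def apply_qc(
    dataset: GenotypeDataset,
    triads: list[Triad],
    thresholds: QCThresholds | None = None,
) -> tuple[GenotypeDataset, list[Triad], QCReport]:
    """Apply sample-level then SNP-level filters.

    Order: sample call rate, founder heterozygosity z (founder mean/SD),
    per-sample Mendel error rate (errors attributed to the trio's offspring);
    failing samples are removed with their triads. SNP statistics are then
    computed on the survivors: call rate, MAF, founders-only HWE exact test,
    per-SNP Mendel error rate. Finally, Mendelian-inconsistent trio genotypes
    at surviving SNPs are set to missing.

    Returns the filtered dataset, the surviving triads (re-indexed into it),
    and a :class:`QCReport`. Idempotent on its own output.
    """
    thresholds = thresholds or QCThresholds()
    g = dataset.genotypes
    n_samples, n_snps = g.shape

    # ---- sample statistics -------------------------------------------------
    obs = g != MISSING
    sample_call = obs.sum(axis=1) / max(n_snps, 1)
    with np.errstate(invalid="ignore"):
        het_rate = np.where(obs.sum(axis=1) > 0, (g == 1).sum(axis=1) / obs.sum(axis=1), np.nan)

    founders = _founder_mask(dataset, triads)
    mu = np.nanmean(het_rate[founders])
    sd = np.nanstd(het_rate[founders], ddof=1) if founders.sum() > 1 else np.nan
    with np.errstate(invalid="ignore"):
        het_z = (het_rate - mu) / sd if np.isfinite(sd) and sd > 0 else np.zeros(n_samples)

    consistent = _mendel_consistent_matrix(dataset, triads)
    countable = np.zeros((len(triads), n_snps), dtype=bool)
    for i, t in enumerate(triads):
        countable[i] = ((g[t.mother_row] != MISSING) & (g[t.father_row] != MISSING)
                        & (g[t.child_row] != MISSING))
    sample_mendel = np.zeros(n_samples)
    for i, t in enumerate(triads):  # errors counted against the offspring
        n_check = countable[i].sum()
        if n_check:
            sample_mendel[t.child_row] = (~consistent[i] & countable[i]).sum() / n_check

    sample_reasons: list[list[str]] = [[] for _ in range(n_samples)]
    for j in range(n_samples):
        if sample_call[j] < thresholds.sample_call_rate_min:
            sample_reasons[j].append("call_rate")
        if founders[j] and np.isfinite(het_z[j]) and abs(het_z[j]) > thresholds.het_sd_window:
            sample_reasons[j].append("het")
        if sample_mendel[j] >= thresholds.sample_mendel_error_max:
            sample_reasons[j].append("mendel")
    sample_pass = np.array([not r for r in sample_reasons])

    sample_table = pd.DataFrame({
        "iid": dataset.samples["iid"].to_numpy(),
        "call_rate": sample_call,
        "het_rate": het_rate,
        "het_z": het_z,
        "mendel_error_rate": sample_mendel,
        "is_founder": founders,
        "pass": sample_pass,
        "reasons": [",".join(r) for r in sample_reasons],
    })

    # remove failing samples and every triad touching them
    keep_rows = np.where(sample_pass)[0]
    kept_ids = set(dataset.samples["iid"].to_numpy()[keep_rows])
    surv = dataset.subset(sample_rows=keep_rows)
    surv_idx = surv.sample_index()
    surviving_triads: list[Triad] = []
    for t in triads:
        if {t.child_id, t.mother_id, t.father_id} <= kept_ids:
            surviving_triads.append(Triad(
                child_id=t.child_id, mother_id=t.mother_id, father_id=t.father_id,
                mother_row=int(surv_idx[t.mother_id]), father_row=int(surv_idx[t.father_id]),
                child_row=int(surv_idx[t.child_id]), dataset=surv,
                affected=t.affected, sex=t.sex, smoking=t.smoking,
                drinking=t.drinking, bmi=t.bmi, covariates_missing=t.covariates_missing,
            ))

    # ---- SNP statistics on survivors ---------------------------------------
    summary = snp_summary(surv)
    founders2 = _founder_mask(surv, surviving_triads)
    gf = surv.genotypes[founders2]
    hwe_p = np.ones(surv.n_snps)
    for k in range(surv.n_snps):
        col = gf[:, k]
        col = col[col != MISSING]
        if col.size == 0:
            hwe_p[k] = np.nan
            continue
        hwe_p[k] = hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                                  int((col == 2).sum()))

    cons2 = _mendel_consistent_matrix(surv, surviving_triads)
    count2 = np.zeros_like(cons2)
    gg = surv.genotypes
    for i, t in enumerate(surviving_triads):
        count2[i] = ((gg[t.mother_row] != MISSING) & (gg[t.father_row] != MISSING)
                     & (gg[t.child_row] != MISSING))
    n_check = count2.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        snp_mendel = np.where(n_check > 0, (~cons2 & count2).sum(axis=0) / n_check, 0.0)

    snp_reasons: list[list[str]] = [[] for _ in range(surv.n_snps)]
    for k in range(surv.n_snps):
        if summary["call_rate"].iloc[k] < thresholds.snp_call_rate_min:
            snp_reasons[k].append("call_rate")
        maf = summary["maf"].iloc[k]
        if not np.isfinite(maf) or maf <= thresholds.maf_min:
            snp_reasons[k].append("maf")
        if np.isfinite(hwe_p[k]) and hwe_p[k] <= thresholds.hwe_p_min:
            snp_reasons[k].append("hwe")
        if snp_mendel[k] >= thresholds.snp_mendel_error_max:
            snp_reasons[k].append("mendel")
    snp_pass = np.array([not r for r in snp_reasons])

    snp_table = summary.assign(
        hwe_p=hwe_p,
        mendel_error_rate=snp_mendel,
        **{"pass": snp_pass},
        reasons=[",".join(r) for r in snp_reasons],
    )

    filtered = surv.subset(snp_cols=np.where(snp_pass)[0])
    if filtered.n_samples == 0 or filtered.n_snps == 0:
        raise ValueError("QC removed all samples or all SNPs; nothing left to analyze")

    # set Mendelian-inconsistent trio genotypes to missing at surviving SNPs
    kept_cols = np.where(snp_pass)[0]
    final_triads: list[Triad] = []
    fidx = filtered.sample_index()
    for t in surviving_triads:
        final_triads.append(Triad(
            child_id=t.child_id, mother_id=t.mother_id, father_id=t.father_id,
            mother_row=int(fidx[t.mother_id]), father_row=int(fidx[t.father_id]),
            child_row=int(fidx[t.child_id]), dataset=filtered,
            affected=t.affected, sex=t.sex, smoking=t.smoking,
            drinking=t.drinking, bmi=t.bmi, covariates_missing=t.covariates_missing,
        ))
    for i_old, t in zip(range(len(surviving_triads)), final_triads):
        bad = ~cons2[i_old, kept_cols] & count2[i_old, kept_cols]
        cols = np.where(bad)[0]
        for c in cols:
            filtered.genotypes[t.mother_row, c] = MISSING
            filtered.genotypes[t.father_row, c] = MISSING
            filtered.genotypes[t.child_row, c] = MISSING

    report = QCReport(snp_table=snp_table, sample_table=sample_table, thresholds=thresholds)
    return filtered, final_triads, report
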