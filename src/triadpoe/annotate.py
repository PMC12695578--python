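"""Post-hoc annotation: gene assignment, mQTL intersection, methylation beta.

A convenience table of the 27 genes in the PIP2-hydrolysis pathway ships with
the package (``data/pip2_genes.tsv``); its spans are approximate GRCh38
intervals intended for quick orientation — supply your own coordinate table
for production annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GeneRegion",
    "load_gene_table",
    "assign_genes",
    "intersect_mqtl",
    "methylation_beta",
    "compare_beta_groups",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRegion:
    """A named 1-based closed genomic interval."""

    gene: str
    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"{self.gene}: start {self.start_bp} > end {self.end_bp}")

    def contains(self, chrom: str, pos: int, flank: int = 0) -> bool:
        return (str(chrom) == str(self.chrom)
                and self.start_bp - flank <= pos <= self.end_bp + flank)


def load_gene_table(path=None) -> list[GeneRegion]:
    """Load a gene coordinate TSV (columns gene, chrom, start, end; 1-based
    closed intervals). Default: the bundled PIP2-pathway table."""
    if path is None:
        with resources.files("triadpoe.data").joinpath("pip2_genes.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", comment="#", dtype={"chrom": str})
    else:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    return [GeneRegion(r.gene, str(r.chrom), int(r.start), int(r.end))
            for r in df.itertuples()]


def assign_genes(snps: pd.DataFrame, regions: list[GeneRegion], flank: int = 0
                 ) -> dict[str, list[str]]:
    """Map each SNP to every region containing its position.

    ``snps`` needs columns ``rsid, chrom, pos``. Positions and regions must
    share a genome build (caller's responsibility; logged as a reminder).
    Returns rsid -> list of gene symbols (empty list if none).
    """
    logger.debug("assign_genes: assuming SNP positions and regions share a genome build")
    out: dict[str, list[str]] = {}
    for row in snps.itertuples():
        hits = [r.gene for r in regions if r.contains(str(row.chrom), int(row.pos), flank)]
        out[row.rsid] = hits
    return out


def intersect_mqtl(snp_ids, mqtl_ids) -> list[str]:
    """Exact-string intersection of rsID lists, preserving snp_ids order.

    Duplicates in either list are removed with a warning.
    """
    snp_list = list(snp_ids)
    mqtl_list = list(mqtl_ids)
    if len(set(snp_list)) != len(snp_list) or len(set(mqtl_list)) != len(mqtl_list):
        warnings.warn("duplicate rsIDs deduplicated before intersection")
    mqtl_set = set(mqtl_list)
    seen: set[str] = set()
    out = []
    for s in snp_list:
        if s in mqtl_set and s not in seen:
            out.append(s)
            seen.add(s)
    logger.info("intersect_mqtl: %d of %d SNPs are mQTLs", len(out), len(set(snp_list)))
    return out


def methylation_beta(m: float, u: float) -> float:
    """Methylation beta-value from probe intensities.

    beta = max(M,0) / (max(M,0) + max(U,0) + 100); negative intensities are
    clamped to zero and the +100 offset keeps the denominator positive, so
    beta always lies in [0, 1).
    """
    m_c = max(float(m), 0.0)
    u_c = max(float(u), 0.0)
    return m_c / (m_c + u_c + 100.0)


def compare_beta_groups(betas: "np.ndarray", groups: "np.ndarray") -> dict:
    """Exploratory two-group comparison of methylation beta-values.

    A generic Welch t-test of beta between two labelled groups (e.g. T2D case
    vs control); provided for convenience only — no specific published model
    is implied.
    """
    from scipy import stats

    betas = np.asarray(betas, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two group labels required")
    a, b = betas[groups == labels[0]], betas[groups == labels[1]]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return {"group_labels": list(labels), "mean_diff": float(a.mean() - b.mean()),
            "t": float(t), "p": float(p)}
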