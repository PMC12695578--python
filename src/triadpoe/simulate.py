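"""Synthetic case-parent triads with known parent-of-origin structure.

The generator draws parental genotypes under Hardy-Weinberg equilibrium at
frequency ``q``, transmits alleles Mendelianly, and ascertains trios on an
affected child via rejection sampling with disease probability
``baseline_b * penetrance`` — exactly the structure the fitting model assumes,
which makes parameter recovery a correctly specified problem. One SNP (the
first by default) is causal; any additional SNPs are null and independent, so
their distribution is unaffected by the ascertainment. Missingness and
Mendelian-error corruption are injected last; a truth record preserves the
latent transmissions and generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeDataset, MISSING, Triad, assemble_triads, write_plink

__all__ = ["SimConfig", "StratumSpec", "simulate_triads", "make_fixture", "FIXTURES"]

_MAX_PROPOSALS = 10_000_000


@dataclass(frozen=True)
class StratumSpec:
    """Per-stratum overrides: triad count and generating relative risks."""

    n_triads: int
    rr_m: float = 1.0
    rr_f: float = 1.0
    rr_dd: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """Generating conditions for one synthetic triad study.

    ``baseline_b`` is the explicit baseline disease probability (it cancels in
    the analysis but is needed generatively); default 0.05 gives a realistic
    lifetime-risk scale. Covariate prevalences (smoking 30%, drinking 30%,
    obesity ~35% in this ascertained T2D setting) are fixed unless strata are
    supplied, in which case the stratum variable is set from the stratum.
    """

    n_triads: int = 200
    q: float = 0.3
    baseline_b: float = 0.05
    rr_m: float = 1.0
    rr_f: float = 1.0
    rr_dd: float = 1.0
    mat1: float = 1.0
    mat2: float = 1.0
    missing_rate: float = 0.0
    mendel_error_rate: float = 0.0
    n_snps: int = 1
    causal_snp: int = 0
    stratum_var: str | None = None
    strata: dict[str, StratumSpec] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie in (0,1)")
        for name in ("missing_rate", "mendel_error_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} outside [0,1]")
        specs = self.strata.values() if self.strata else [
            StratumSpec(self.n_triads, self.rr_m, self.rr_f, self.rr_dd)]
        for s in specs:
            max_pen = (max(1.0, s.rr_m) * max(1.0, s.rr_f) * max(1.0, s.rr_dd)
                       * max(1.0, self.mat1, self.mat2))
            if self.baseline_b * max_pen > 1.0:
                raise ValueError(
                    f"baseline_b*max_penetrance = {self.baseline_b * max_pen:.3f} > 1; "
                    "lower baseline_b or the relative risks")
        if self.strata and self.stratum_var is None:
            raise ValueError("strata given without stratum_var")


def _draw_ascertained(rng: np.random.Generator, n: int, q: float, b: float,
                      rr_m: float, rr_f: float, rr_dd: float,
                      mat1: float, mat2: float
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Rejection-sample n case trios at the causal SNP.

    Returns (g_M, g_F, c_m, c_f) arrays; child genotype = c_m + c_f.
    """
    gm_l, gf_l, cm_l, cf_l = [], [], [], []
    got = 0
    proposed = 0
    while got < n:
        if proposed >= _MAX_PROPOSALS:
            raise RuntimeError(
                "ascertainment unreachable: acceptance probability ~ 0 "
                f"after {proposed} proposals")
        batch = max(1024, int((n - got) * 2.5 / max(b, 1e-9)))
        batch = min(batch, _MAX_PROPOSALS - proposed, 2_000_000)
        proposed += batch
        gm = rng.binomial(2, q, size=batch)
        gf = rng.binomial(2, q, size=batch)
        # transmitted allele: forced for homozygotes, fair coin for hets
        cm = np.where(gm == 2, 1, np.where(gm == 0, 0, rng.integers(0, 2, size=batch)))
        cf = np.where(gf == 2, 1, np.where(gf == 0, 0, rng.integers(0, 2, size=batch)))
        mat = np.choose(gm, [1.0, mat1, mat2])
        pen = (rr_m ** cm) * (rr_f ** cf) * (rr_dd ** (cm * cf)) * mat
        affected = rng.random(batch) < b * pen
        idx = np.where(affected)[0][: n - got]
        gm_l.append(gm[idx]); gf_l.append(gf[idx])
        cm_l.append(cm[idx]); cf_l.append(cf[idx])
        got += len(idx)
    return (np.concatenate(gm_l), np.concatenate(gf_l),
            np.concatenate(cm_l), np.concatenate(cf_l))


def _null_snp(rng: np.random.Generator, n: int, q: float) -> tuple[np.ndarray, ...]:
    gm = rng.binomial(2, q, size=n)
    gf = rng.binomial(2, q, size=n)
    cm = np.where(gm == 2, 1, np.where(gm == 0, 0, rng.integers(0, 2, size=n)))
    cf = np.where(gf == 2, 1, np.where(gf == 0, 0, rng.integers(0, 2, size=n)))
    return gm, gf, cm, cf


def _inject_mendel_errors(rng: np.random.Generator, geno: np.ndarray,
                          trio_rows: np.ndarray, rate: float) -> list[dict]:
    """Flip one member of randomly chosen trios to an incompatible value at the
    causal-SNP column convention: corruption applies per (triad, SNP) column 0..n.

    ``geno`` is (n_samples, n_snps); ``trio_rows`` is (n_triads, 3) row indices
    (mother, father, child). Trios where no single flip creates an
    inconsistency (e.g. all-heterozygous) are skipped. Returns the injection log.
    """
    from .qc import _MENDEL_OK

    injected = []
    n_snps = geno.shape[1]
    for i, (rm, rf, rc) in enumerate(trio_rows):
        for j in range(n_snps):
            if rng.random() >= rate:
                continue
            trio = [int(geno[rm, j]), int(geno[rf, j]), int(geno[rc, j])]
            if MISSING in trio:
                continue
            members = rng.permutation(3)
            done = False
            for mem in members:
                vals = [v for v in (0, 1, 2) if v != trio[mem]]
                rng.shuffle(vals)
                for v in vals:
                    cand = trio.copy()
                    cand[mem] = v
                    if not _MENDEL_OK[cand[0], cand[1], cand[2]]:
                        row = (rm, rf, rc)[mem]
                        geno[row, j] = v
                        injected.append({"triad": i, "snp": j, "member": int(mem),
                                         "old": trio[mem], "new": v})
                        done = True
                        break
                if done:
                    break
    return injected


def simulate_triads(config: SimConfig
                    ) -> tuple[GenotypeDataset, pd.DataFrame, dict]:
    """Generate an ascertained triad study.

    Returns (dataset, covariates, truth) where ``truth`` records the generating
    parameters, per-triad latent transmissions at the causal SNP, stratum
    labels, and the pre-corruption genotype matrix (as a nested list) so the
    corruption is auditable.
    """
    rng = np.random.default_rng(config.seed)
    strata = config.strata or {
        "all": StratumSpec(config.n_triads, config.rr_m, config.rr_f, config.rr_dd)}

    gm_c, gf_c, cm_c, cf_c, labels = [], [], [], [], []
    for label, spec in strata.items():
        gm, gf, cm, cf = _draw_ascertained(
            rng, spec.n_triads, config.q, config.baseline_b,
            spec.rr_m, spec.rr_f, spec.rr_dd, config.mat1, config.mat2)
        gm_c.append(gm); gf_c.append(gf); cm_c.append(cm); cf_c.append(cf)
        labels += [label] * spec.n_triads
    gm = np.concatenate(gm_c); gf = np.concatenate(gf_c)
    cm = np.concatenate(cm_c); cf = np.concatenate(cf_c)
    n = len(gm)

    geno = np.zeros((3 * n, config.n_snps), dtype=np.int8)
    latent = {"causal": {"c_m": cm.tolist(), "c_f": cf.tolist()}, "null": {}}
    for j in range(config.n_snps):
        if j == config.causal_snp:
            m, f, tm, tf = gm, gf, cm, cf
        else:
            m, f, tm, tf = _null_snp(rng, n, config.q)
            latent["null"][str(j)] = {"c_m": tm.tolist(), "c_f": tf.tolist()}
        geno[0::3, j] = m
        geno[1::3, j] = f
        geno[2::3, j] = tm + tf

    fam = pd.DataFrame({
        "fid": [f"F{i:05d}" for i in range(n) for _ in range(3)],
        "iid": [f"{role}{i:05d}" for i in range(n) for role in ("M", "P", "C")],
        "father": [x for i in range(n) for x in ("0", "0", f"P{i:05d}")],
        "mother": [x for i in range(n) for x in ("0", "0", f"M{i:05d}")],
        "sex": [x for _ in range(n) for x in ("2", "1", "0")],
        "affection": [x for _ in range(n) for x in ("1", "1", "2")],
    })
    child_sex = rng.integers(1, 3, size=n)  # 1 male / 2 female
    fam.loc[2::3, "sex"] = child_sex.astype(str)

    snps = pd.DataFrame({
        "rsid": [f"rs{j + 1:06d}" for j in range(config.n_snps)],
        "chrom": "1",
        "pos": 1000 + 1000 * np.arange(config.n_snps),
        "allele1": "A",
        "allele2": "G",
    })

    pristine = geno.copy()

    # covariates for the affected children
    child_ids = [f"C{i:05d}" for i in range(n)]
    smoking = rng.binomial(1, 0.30, size=n)
    drinking = rng.binomial(1, 0.30, size=n)
    if config.stratum_var == "bmi_class":
        bmi = np.where(np.asarray(labels) == ">=28",
                       rng.normal(30.5, 1.8, size=n).clip(28.0, 45.0),
                       rng.normal(24.0, 2.0, size=n).clip(16.0, 27.9))
    else:
        bmi = rng.normal(25.5, 3.5, size=n).clip(15.0, 45.0)
    if config.stratum_var == "smoking":
        smoking = (np.asarray(labels) == "yes").astype(int)
    if config.stratum_var == "drinking":
        drinking = (np.asarray(labels) == "yes").astype(int)
    sex_lab = np.where(child_sex == 1, "male", "female")
    if config.stratum_var == "sex":
        sex_lab = np.asarray(labels)
    covariates = pd.DataFrame({
        "individual_id": child_ids,
        "affected": 1,
        "smoking": smoking,
        "drinking": drinking,
        "bmi": np.round(bmi, 1),
        "sex": sex_lab,
    })

    # corruption: Mendelian errors first, then missingness
    trio_rows = np.column_stack([np.arange(n) * 3, np.arange(n) * 3 + 1, np.arange(n) * 3 + 2])
    injected = []
    if config.mendel_error_rate > 0:
        injected = _inject_mendel_errors(rng, geno, trio_rows, config.mendel_error_rate)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    dataset = GenotypeDataset(samples=fam, snps=snps, genotypes=geno)
    truth = {
        "config": {**asdict(config),
                   "strata": {k: asdict(v) for k, v in (config.strata or {}).items()} or None},
        "stratum_labels": labels,
        "latent_transmissions": latent,
        "mendel_errors_injected": injected,
        "pristine_genotypes": pristine.tolist(),
    }
    return dataset, covariates, truth


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

def _qc_violations_config() -> SimConfig:
    return SimConfig(n_triads=100, q=0.3, baseline_b=0.05, n_snps=40, seed=20240)


FIXTURES: dict[str, SimConfig] = {
    "clean_null": SimConfig(n_triads=200, q=0.3, baseline_b=0.05, n_snps=5, seed=11),
    "strong_maternal": SimConfig(n_triads=200, q=0.3, baseline_b=0.05,
                                 rr_m=4.0, rr_f=1.0, n_snps=1, seed=12),
    "strong_paternal": SimConfig(n_triads=200, q=0.3, baseline_b=0.05,
                                 rr_m=1.0, rr_f=4.0, n_snps=1, seed=13),
    "bmi_interaction": SimConfig(
        q=0.3, baseline_b=0.02, n_snps=1, seed=14, stratum_var="bmi_class",
        strata={">=28": StratumSpec(500, rr_m=6.0, rr_f=1.0 / 6.0),
                "<28": StratumSpec(500, rr_m=2.0, rr_f=1.0)}),
    "qc_violations": _qc_violations_config(),
}


def make_fixture(name: str, out_dir) -> dict:
    """Write a named deterministic fixture as PLINK + covariate TSV + truth JSON.

    Returns the truth record (with planted-violation lists for qc_violations).
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = FIXTURES[name]
    dataset, covariates, truth = simulate_triads(config)

    if name == "qc_violations":
        truth = _plant_qc_violations(dataset, covariates, truth)

    write_plink(dataset, out_dir / name)
    covariates.to_csv(out_dir / f"{name}.cov.tsv", sep="\t", index=False)
    slim = {k: v for k, v in truth.items() if k != "pristine_genotypes"}
    (out_dir / f"{name}.truth.json").write_text(json.dumps(slim, indent=1))
    return truth


def _plant_qc_violations(dataset: GenotypeDataset, covariates: pd.DataFrame,
                         truth: dict) -> dict:
    """Plant one violation of each SNP- and sample-level filter.

    SNP 1: low MAF; SNP 2: low call rate; SNP 3: HWE failure (all-het
    parents); SNP 4: 20% Mendelian errors. Sample plants: one father with 20%
    missing genotypes; one mother heterozygous at every SNP (het outlier); one
    child corrupted to ~10% Mendelian errors.
    """
    rng = np.random.default_rng(990)
    g = dataset.genotypes
    n_samples, n_snps = g.shape
    n_triads = n_samples // 3
    from .qc import _MENDEL_OK

    # SNP 1: rare allele (freq ~0.005), Mendelian-consistent
    g[:, 1] = 0
    carriers = rng.choice(np.arange(n_triads), size=2, replace=False)
    for t in carriers:
        g[3 * t, 1] = 1       # het mother
        g[3 * t + 2, 1] = rng.integers(0, 2)  # child 0 or 1: consistent

    # SNP 2: low call rate (8% missing)
    mask = rng.random(n_samples) < 0.08
    g[mask, 2] = MISSING

    # SNP 3: gross heterozygote excess among parents
    g[0::3, 3] = 1
    g[1::3, 3] = 1
    g[2::3, 3] = rng.integers(0, 3, size=n_triads)  # het parents: any child ok

    # SNP 4: 20% of trios made Mendelian-inconsistent
    bad_trios = rng.choice(np.arange(n_triads), size=n_triads // 5, replace=False)
    for t in bad_trios:
        rows = (3 * t, 3 * t + 1, 3 * t + 2)
        trio = [int(g[r, 4]) for r in rows]
        for mem in rng.permutation(3):
            found = False
            for v in rng.permutation([0, 1, 2]):
                cand = trio.copy()
                cand[mem] = int(v)
                if not _MENDEL_OK[cand[0], cand[1], cand[2]]:
                    g[rows[mem], 4] = int(v)
                    found = True
                    break
            if found:
                break

    # sample plants use trios 90-92, away from the SNP plants' random picks
    low_call_row = 3 * 90 + 1       # father of trio 90
    cols = rng.choice(np.arange(n_snps), size=int(0.2 * n_snps), replace=False)
    g[low_call_row, cols] = MISSING

    het_row = 3 * 91                # mother of trio 91: heterozygous everywhere
    g[het_row, :] = 1

    mendel_child_row = 3 * 92 + 2   # child of trio 92: ~10% inconsistent SNPs
    bad_cols = rng.choice(np.arange(5, n_snps), size=max(4, n_snps // 10), replace=False)
    planted_cols = []
    for j in bad_cols:
        gm_, gf_ = int(g[3 * 92, j]), int(g[3 * 92 + 1, j])
        if MISSING in (gm_, gf_):
            continue
        for v in rng.permutation([0, 1, 2]):
            if not _MENDEL_OK[gm_, gf_, int(v)]:
                g[mendel_child_row, j] = int(v)
                planted_cols.append(int(j))
                break

    snp_ids = dataset.snps["rsid"].to_numpy()
    iids = dataset.samples["iid"].to_numpy()
    truth["planted"] = {
        "bad_snps": {snp_ids[1]: "maf", snp_ids[2]: "call_rate",
                     snp_ids[3]: "hwe", snp_ids[4]: "mendel"},
        "bad_samples": {iids[low_call_row]: "call_rate",
                        iids[het_row]: "het",
                        iids[mendel_child_row]: "mendel"},
    }
    return truth


def dataset_triads(dataset: GenotypeDataset, covariates: pd.DataFrame) -> list[Triad]:
    """Convenience: assemble triads from a simulated dataset."""
    return assemble_triads(dataset, covariates)


def genotype_triples(dataset: GenotypeDataset, snp_col: int = 0) -> np.ndarray:
    """(n_triads, 3) array of (g_M, g_F, g_C) for a simulated dataset.

    Relies on the simulator's fixed mother/father/child row layout; for
    general pedigrees use :func:`~triadpoe.io.assemble_triads`.
    """
    g = dataset.genotypes
    return np.column_stack([g[0::3, snp_col], g[1::3, snp_col], g[2::3, snp_col]]).astype(int)
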