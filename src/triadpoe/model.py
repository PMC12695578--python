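"""Parent-of-origin relative-risk estimation from case-parent triads.

The model
---------
For a biallelic SNP with alleles a1/a2 and population frequency ``q`` of a2,
parental genotypes are assumed to follow Hardy-Weinberg proportions and mate
independently; transmissions are Mendelian. The affected child's disease
probability is multiplicative in parent-of-origin-specific relative risks:

    P(D | origins, g_M) = B * rr_m^[maternal a2] * rr_f^[paternal a2]
                            * rr_dd^[both a2]
                            * mat1^[g_M = 1] * mat2^[g_M = 2]

``rr_m`` / ``rr_f`` are the relative risks of one copy of a2 when transmitted
maternally / paternally, ``rr_dd`` lets homozygous children deviate from the
multiplicative dose model, and the optional maternal-genotype effects
``mat1``/``mat2`` capture risk from the mother's own genotype. The baseline
``B`` cancels in the likelihood conditional on the child being affected and is
not a parameter.

Because all triads are ascertained on an affected child, the likelihood of an
observed trio (g_M, g_F, g_C) is the ratio of its penetrance-weighted
HWE/Mendelian probability to the same sum over *all* Mendelian trio
configurations. Heterozygous-origin ambiguity (all three members het) and
single missing member genotypes are marginalized inside the likelihood.

The parent-of-origin effect is reported as the ratio ``rr_m / rr_f`` with a
Wald confidence interval on the log scale; ``rr_m/rr_f > 1`` means the allele
carries more risk when maternally inherited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

from .io import MISSING, Triad

__all__ = [
    "OriginConfig",
    "POEParams",
    "POEResults",
    "TriadPOEModel",
    "enumerate_origins",
    "penetrance_factor",
    "triad_loglik",
    "fit_poe",
    "classify_transmission",
]

# ---------------------------------------------------------------------------
# latent-origin bookkeeping
# ---------------------------------------------------------------------------

A1, A2 = "a1", "a2"


@dataclass(frozen=True)
class OriginConfig:
    """A latent assignment of the allele each parent transmitted.

    ``c_m``/``c_f`` name the maternally/paternally transmitted allele;
    ``prior_weight`` is the product of Mendelian transmission probabilities
    (1 for a homozygous parent, 1/2 per heterozygous parent).
    """

    c_m: str
    c_f: str
    prior_weight: float


def _transmissible(g: int) -> list[tuple[int, float]]:
    """(allele2-count of transmitted allele, Mendelian probability)."""
    return {0: [(0, 1.0)], 1: [(0, 0.5), (1, 0.5)], 2: [(1, 1.0)]}[g]


def enumerate_origins(g_m: int, g_f: int, g_c: int) -> list[OriginConfig]:
    """All origin configurations consistent with an observed trio.

    Returns the empty list for a Mendelian-inconsistent triple (the caller
    treats the trio as missing at that SNP).
    """
    if any(g not in (0, 1, 2) for g in (g_m, g_f, g_c)):
        raise ValueError("genotype codes must be fully observed and in {0,1,2}")
    out = []
    for cm, wm in _transmissible(g_m):
        for cf, wf in _transmissible(g_f):
            if cm + cf == g_c:
                out.append(OriginConfig(A2 if cm else A1, A2 if cf else A1, wm * wf))
    return out


# static enumeration of every (g_M, g_F, c_m, c_f): 16 configurations
_CFG_M, _CFG_F, _CFG_CM, _CFG_CF, _CFG_W = [], [], [], [], []
for _gm in range(3):
    for _gf in range(3):
        for _cm, _wm in _transmissible(_gm):
            for _cf, _wf in _transmissible(_gf):
                _CFG_M.append(_gm)
                _CFG_F.append(_gf)
                _CFG_CM.append(_cm)
                _CFG_CF.append(_cf)
                _CFG_W.append(_wm * _wf)
_CFG_M = np.array(_CFG_M)
_CFG_F = np.array(_CFG_F)
_CFG_CM = np.array(_CFG_CM)
_CFG_CF = np.array(_CFG_CF)
_CFG_C = _CFG_CM + _CFG_CF
_CFG_W = np.array(_CFG_W)
_CFG_DD = _CFG_CM * _CFG_CF

MENDELIAN_TRIPLES: list[tuple[int, int, int]] = sorted(
    {(int(m), int(f), int(c)) for m, f, c in zip(_CFG_M, _CFG_F, _CFG_C)}
)  # the 15 Mendelian-consistent ordered trio genotype triples


# ---------------------------------------------------------------------------
# parameters and penetrance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class POEParams:
    """Allele frequency and relative-risk parameters.

    All relative risks are per the model in the module docstring; the baseline
    is intentionally absent (it cancels in the ascertainment-conditional
    likelihood).
    """

    q: float
    rr_m: float = 1.0
    rr_f: float = 1.0
    rr_dd: float = 1.0
    mat1: float = 1.0
    mat2: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q={self.q} must lie strictly in (0,1)")
        for name in ("rr_m", "rr_f", "rr_dd", "mat1", "mat2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ratio(self) -> float:
        """The parent-of-origin effect rr_m / rr_f."""
        return self.rr_m / self.rr_f


def penetrance_factor(config: OriginConfig, g_m: int, params: POEParams) -> float:
    """Relative penetrance of an affected child under one origin configuration
    (baseline B omitted)."""
    cm = config.c_m == A2
    cf = config.c_f == A2
    out = (params.rr_m if cm else 1.0) * (params.rr_f if cf else 1.0)
    if cm and cf:
        out *= params.rr_dd
    if g_m == 1:
        out *= params.mat1
    elif g_m == 2:
        out *= params.mat2
    return out


def _numerator_table(params: POEParams) -> np.ndarray:
    """3x3x3 array: joint HWE/Mendelian/penetrance weight of each (M,F,C),
    summed over latent origins. Entry is zero for non-Mendelian triples."""
    q = params.q
    hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    mat = np.array([1.0, params.mat1, params.mat2])
    pen = (params.rr_m ** _CFG_CM) * (params.rr_f ** _CFG_CF) * (params.rr_dd ** _CFG_DD)
    contrib = hwe[_CFG_M] * hwe[_CFG_F] * _CFG_W * pen * mat[_CFG_M]
    table = np.zeros((3, 3, 3))
    np.add.at(table, (_CFG_M, _CFG_F, _CFG_C), contrib)
    return table


def conditional_triple_probs(params: POEParams) -> np.ndarray:
    """3x3x3 array of P(g_M, g_F, g_C | child affected); sums to 1."""
    table = _numerator_table(params)
    return table / table.sum()


# ---------------------------------------------------------------------------
# sufficient statistics and likelihood
# ---------------------------------------------------------------------------

def _pattern_counts(genotype_triples: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Collapse trios to unique observation patterns with counts.

    ``genotype_triples`` is (n, 3) int with MISSING = -1. Trios with >= 2
    missing members are dropped; Mendelian-inconsistent fully observed trios
    are dropped (treated as missing, mirroring QC's masking). Returns
    (patterns (k,3), counts (k,), n_used).
    """
    g = np.asarray(genotype_triples, dtype=int)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of (g_M, g_F, g_C) codes")
    n_missing = (g == MISSING).sum(axis=1)
    keep = n_missing <= 1
    g = g[keep]
    full = (g != MISSING).all(axis=1)
    ok = np.ones(len(g), dtype=bool)
    if full.any():
        from .qc import _MENDEL_OK  # shared consistency table
        sub = g[full]
        ok[np.where(full)[0]] = _MENDEL_OK[sub[:, 0], sub[:, 1], sub[:, 2]]
    g = g[ok]
    if len(g) == 0:
        return np.zeros((0, 3), dtype=int), np.zeros(0), 0
    patterns, counts = np.unique(g, axis=0, return_counts=True)
    return patterns, counts.astype(float), int(counts.sum())


def _pattern_logprobs(patterns: np.ndarray, params: POEParams) -> np.ndarray:
    """log P(observed pattern | D) for each unique pattern (missing members
    marginalized)."""
    table = _numerator_table(params)
    z = table.sum()
    out = np.empty(len(patterns))
    for i, (gm, gf, gc) in enumerate(patterns):
        if gm == MISSING:
            num = table[:, gf, gc].sum()
        elif gf == MISSING:
            num = table[gm, :, gc].sum()
        elif gc == MISSING:
            num = table[gm, gf, :].sum()
        else:
            num = table[gm, gf, gc]
        out[i] = np.log(num) - np.log(z) if num > 0 else -np.inf
    return out


def triads_to_array(triads: list[Triad], snp_col: int = 0) -> np.ndarray:
    """Extract the (n, 3) genotype-triple array at one SNP column."""
    return np.array([t.genotypes(snp_col) for t in triads], dtype=int)


def triad_loglik(triads, params: POEParams, snp_col: int = 0) -> float:
    """Marginal log-likelihood of the triads at one SNP, conditional on every
    child being affected.

    ``triads`` may be a list of :class:`~triadpoe.io.Triad` or an (n, 3) array
    of (g_M, g_F, g_C) codes. Trios with a single missing member are
    marginalized over the unobserved genotype; trios with >= 2 missing members
    or Mendelian inconsistency are excluded.
    """
    arr = triads if isinstance(triads, np.ndarray) else triads_to_array(triads, snp_col)
    patterns, counts, n_used = _pattern_counts(arr)
    if n_used == 0:
        raise ValueError("no informative triads")
    return float(counts @ _pattern_logprobs(patterns, params))


# ---------------------------------------------------------------------------
# the model / results objects
# ---------------------------------------------------------------------------

def _pack(params: POEParams, free_dd: bool, maternal: bool) -> np.ndarray:
    th = [np.log(params.q / (1 - params.q)), np.log(params.rr_m), np.log(params.rr_f)]
    if free_dd:
        th.append(np.log(params.rr_dd))
    if maternal:
        th += [np.log(params.mat1), np.log(params.mat2)]
    return np.array(th)


def _unpack(theta: np.ndarray, free_dd: bool, maternal: bool) -> POEParams:
    q = 1.0 / (1.0 + np.exp(-theta[0]))
    i = 3
    rr_dd = 1.0
    if free_dd:
        rr_dd = float(np.exp(theta[i]))
        i += 1
    mat1 = mat2 = 1.0
    if maternal:
        mat1, mat2 = float(np.exp(theta[i])), float(np.exp(theta[i + 1]))
    return POEParams(q=float(np.clip(q, 1e-12, 1 - 1e-12)),
                     rr_m=float(np.exp(theta[1])), rr_f=float(np.exp(theta[2])),
                     rr_dd=rr_dd, mat1=mat1, mat2=mat2)


class TriadPOEModel:
    """Maximum-likelihood model for parent-of-origin effects at one SNP.

    Parameters
    ----------
    genotype_triples : array-like of shape (n, 3)
        (g_M, g_F, g_C) allele2 dosages per triad, -1 for missing.
    free_rr_dd : bool
        Estimate the double-dose deviation (default) or fix it at 1.
    maternal_effects : bool
        Also estimate the mother's own genotype effects mat1/mat2
        (default off; fragile at small n).
    min_informative_triads : int
        Minimum Mendelian-consistent trios with <= 1 missing member.
    """

    def __init__(self, genotype_triples, *, free_rr_dd: bool = True,
                 maternal_effects: bool = False, min_informative_triads: int = 10):
        arr = np.asarray(genotype_triples, dtype=int)
        self.patterns, self.counts, self.n_used = _pattern_counts(arr)
        self.n_total = len(arr)
        self.free_rr_dd = free_rr_dd
        self.maternal_effects = maternal_effects
        self.min_informative_triads = min_informative_triads
        if self.n_used < min_informative_triads:
            raise ValueError(
                f"only {self.n_used} informative triads "
                f"(need >= {min_informative_triads})")

    @classmethod
    def from_triads(cls, triads: list[Triad], snp_col: int = 0, **kw) -> "TriadPOEModel":
        return cls(triads_to_array(triads, snp_col), **kw)

    @classmethod
    def from_dataset(cls, dataset, triads: list[Triad], rsid: str, **kw) -> "TriadPOEModel":
        col = int(np.where(dataset.snps["rsid"].to_numpy() == rsid)[0][0])
        return cls.from_triads(triads, snp_col=col, **kw)

    # -- likelihood in the unconstrained parameterization --------------------

    def loglike(self, theta: np.ndarray) -> float:
        params = _unpack(np.asarray(theta, float), self.free_rr_dd, self.maternal_effects)
        return float(self.counts @ _pattern_logprobs(self.patterns, params))

    def _neg_loglike(self, theta: np.ndarray) -> float:
        ll = self.loglike(theta)
        return 1e12 if not np.isfinite(ll) else -ll

    def _neg_mean_loglike(self, theta: np.ndarray) -> float:
        # optimizing the per-triad mean keeps gradient tolerances n-invariant
        return self._neg_loglike(theta) / self.n_used

    def _start_points(self) -> list[np.ndarray]:
        # naive allele2 frequency from observed parental genotypes
        par = self.patterns[:, :2]
        w = np.repeat(self.counts, 2)
        flat = par.reshape(-1)
        obs = flat != MISSING
        q0 = float(np.clip((flat[obs] * w[obs]).sum() / (2 * w[obs].sum()), 0.02, 0.98)) \
            if obs.any() else 0.5
        base = POEParams(q=q0)
        skew = np.exp(0.7)
        return [
            _pack(base, self.free_rr_dd, self.maternal_effects),
            _pack(replace(base, rr_m=skew), self.free_rr_dd, self.maternal_effects),
            _pack(replace(base, rr_f=skew), self.free_rr_dd, self.maternal_effects),
        ]

    # -- estimation -----------------------------------------------------------

    def fit(self, method: str = "bfgs", *, maxiter: int = 500,
            gtol: float = 1e-6, lltol: float = 1e-8,
            n_starts: int = 3, start_params: POEParams | None = None) -> "POEResults":
        """Maximize the marginal likelihood.

        ``method='bfgs'`` runs quasi-Newton maximization from multiple starts;
        ``method='em'`` runs expectation-maximization over the latent origins
        and missing genotypes. Both reach the same maximum on regular data.
        """
        starts = ([_pack(start_params, self.free_rr_dd, self.maternal_effects)]
                  if start_params is not None else self._start_points()[:max(1, n_starts)])
        best_theta, best_ll, converged, n_iter = None, -np.inf, False, 0
        for theta0 in starts:
            if method == "em":
                theta, ll, ok, it = self._fit_em(theta0, maxiter=maxiter, lltol=lltol)
            elif method == "bfgs":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = optimize.minimize(self._neg_mean_loglike, theta0, method="BFGS",
                                            options={"maxiter": maxiter, "gtol": gtol})
                theta, ll, ok, it = res.x, -res.fun * self.n_used, bool(res.success), res.nit
                # BFGS can report failure on precision loss at the optimum
                if not ok and np.linalg.norm(res.jac, np.inf) < 1e-4:
                    ok = True
            else:
                raise ValueError(f"unknown method {method!r}")
            if ll > best_ll:
                best_theta, best_ll, converged, n_iter = theta, ll, ok, it
        return self._results(best_theta, best_ll, converged, n_iter, method)

    def _fit_em(self, theta0, *, maxiter=500, lltol=1e-8):
        """EM: E-step computes posterior expectations of the complete-data
        sufficient statistics over (g_M, g_F, c_m, c_f); the M-step maximizes
        the resulting Q function (which retains the ascertainment normalizer)."""
        theta = theta0.copy()
        ll_prev = self.loglike(theta)
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            stats_e = self._e_step(theta)
            theta = self._m_step(stats_e, theta)
            ll = self.loglike(theta)
            if abs(ll - ll_prev) <= lltol * (abs(ll_prev) + 1.0):
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        return theta, ll_prev, converged, it

    def _e_step(self, theta):
        params = _unpack(theta, self.free_rr_dd, self.maternal_effects)
        q = params.q
        hwe = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
        mat = np.array([1.0, params.mat1, params.mat2])
        pen = (params.rr_m ** _CFG_CM) * (params.rr_f ** _CFG_CF) * (params.rr_dd ** _CFG_DD)
        base = hwe[_CFG_M] * hwe[_CFG_F] * _CFG_W * pen * mat[_CFG_M]
        # expected counts of: parent genotype classes, cm, cf, cm*cf, g_M classes
        e = {"par_g": np.zeros(3), "cm": 0.0, "cf": 0.0, "dd": 0.0, "matg": np.zeros(3)}
        for (gm, gf, gc), cnt in zip(self.patterns, self.counts):
            mask = np.ones(len(base), dtype=bool)
            if gm != MISSING:
                mask &= _CFG_M == gm
            if gf != MISSING:
                mask &= _CFG_F == gf
            if gc != MISSING:
                mask &= _CFG_C == gc
            w = base * mask
            w = w / w.sum()
            for gcl in range(3):
                e["par_g"][gcl] += cnt * (w[(_CFG_M == gcl)].sum() + w[(_CFG_F == gcl)].sum())
                e["matg"][gcl] += cnt * w[(_CFG_M == gcl)].sum()
            e["cm"] += cnt * (w * _CFG_CM).sum()
            e["cf"] += cnt * (w * _CFG_CF).sum()
            e["dd"] += cnt * (w * _CFG_DD).sum()
        e["n"] = float(self.counts.sum())
        return e

    def _m_step(self, e, theta0):
        def neg_q(theta):
            params = _unpack(theta, self.free_rr_dd, self.maternal_effects)
            q = params.q
            log_hwe = np.log([(1 - q) ** 2, 2 * q * (1 - q), q * q])
            log_mat = np.log([1.0, params.mat1, params.mat2])
            val = (e["par_g"] @ log_hwe + e["matg"] @ log_mat
                   + e["cm"] * np.log(params.rr_m) + e["cf"] * np.log(params.rr_f)
                   + e["dd"] * np.log(params.rr_dd)
                   - e["n"] * np.log(_numerator_table(params).sum()))
            return -val if np.isfinite(val) else 1e12
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(neg_q, theta0, method="BFGS", options={"maxiter": 200})
        return res.x

    # -- results --------------------------------------------------------------

    def _results(self, theta, llf, converged, n_iter, method):
        params = _unpack(theta, self.free_rr_dd, self.maternal_effects)
        names = ["logit_q", "log_rr_m", "log_rr_f"]
        if self.free_rr_dd:
            names.append("log_rr_dd")
        if self.maternal_effects:
            names += ["log_mat1", "log_mat2"]
        cov = None
        singular = False
        try:
            hess = approx_hess1(theta, self._neg_mean_loglike) * self.n_used
            cov = np.linalg.inv(hess)
            if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
                singular = True
                cov = None
        except np.linalg.LinAlgError:
            singular = True
        return POEResults(model=self, theta=np.asarray(theta, float), params=params,
                          param_names=names, cov_log=cov, llf=float(llf),
                          converged=bool(converged), singular=singular,
                          n_iter=int(n_iter), method=method)


@dataclass
class POEResults:
    """MLE of the triad POE model with uncertainty and the POE ratio test."""

    model: TriadPOEModel
    theta: np.ndarray
    params: POEParams
    param_names: list[str]
    cov_log: np.ndarray | None
    llf: float
    converged: bool
    singular: bool
    n_iter: int
    method: str

    @property
    def n_triads_used(self) -> int:
        return self.model.n_used

    @property
    def ratio(self) -> float:
        """Point estimate of the parent-of-origin effect rr_m / rr_f."""
        return self.params.ratio

    @property
    def log_ratio(self) -> float:
        return float(np.log(self.params.rr_m) - np.log(self.params.rr_f))

    @property
    def log_ratio_se(self) -> float:
        if self.cov_log is None:
            return np.nan
        i, j = self.param_names.index("log_rr_m"), self.param_names.index("log_rr_f")
        var = self.cov_log[i, i] + self.cov_log[j, j] - 2 * self.cov_log[i, j]
        return float(np.sqrt(var)) if var > 0 else np.nan

    def ratio_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        """Wald confidence interval for rr_m/rr_f on the log scale."""
        se = self.log_ratio_se
        if not np.isfinite(se):
            return (np.nan, np.nan)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = self.log_ratio - zcrit * se, self.log_ratio + zcrit * se
        return (float(np.exp(lo)), float(np.exp(hi)))

    @property
    def p_poe(self) -> float:
        """Two-sided Wald p-value for rr_m = rr_f."""
        se = self.log_ratio_se
        if not np.isfinite(se) or se == 0:
            return np.nan
        z = self.log_ratio / se
        return float(2 * stats.norm.sf(abs(z)))

    def p_poe_lrt(self) -> float:
        """Likelihood-ratio alternative: refit with rr_m = rr_f constrained."""
        ll_alt = self.llf
        ll_null = _fit_constrained_equal_rr(self.model)
        lr = max(0.0, 2 * (ll_alt - ll_null))
        return float(stats.chi2.sf(lr, df=1))

    def summary(self) -> str:
        q = self.params.q
        lines = [
            "Case-parent triad parent-of-origin model",
            "=" * 56,
            f"triads used:        {self.n_triads_used} of {self.model.n_total}",
            f"method:             {self.method} "
            f"({'converged' if self.converged else 'NOT converged'}, {self.n_iter} iter)",
            f"log-likelihood:     {self.llf:.4f}",
            "-" * 56,
            f"allele2 freq q:     {q:.4f}",
            f"RR maternal:        {self.params.rr_m:.4f}",
            f"RR paternal:        {self.params.rr_f:.4f}",
            f"RR double-dose:     {self.params.rr_dd:.4f}"
            + ("" if self.model.free_rr_dd else "  (fixed)"),
        ]
        if self.model.maternal_effects:
            lines += [f"maternal geno RR1:  {self.params.mat1:.4f}",
                      f"maternal geno RR2:  {self.params.mat2:.4f}"]
        lo, hi = self.ratio_ci()
        lines += [
            "-" * 56,
            f"POE ratio RRm/RRf:  {self.ratio:.4f}  (95% CI {lo:.4f} - {hi:.4f})",
            f"P (POE, Wald):      {self.p_poe:.4g}",
            "=" * 56,
        ]
        if self.singular:
            lines.insert(-1, "WARNING: singular information matrix; no CI available")
        return "\n".join(lines)

    def to_row(self) -> dict:
        lo, hi = self.ratio_ci()
        return {
            "n_triads": self.n_triads_used,
            "ratio": self.ratio, "ci_low": lo, "ci_high": hi,
            "p_poe": self.p_poe, "converged": self.converged,
        }


def _fit_constrained_equal_rr(model: TriadPOEModel) -> float:
    """Max loglik under rr_m = rr_f (shared log-RR), for the LRT option."""
    free_dd, maternal = model.free_rr_dd, model.maternal_effects

    def neg(theta_c):
        theta = np.concatenate([[theta_c[0], theta_c[1], theta_c[1]], theta_c[2:]])
        return model._neg_loglike(theta)

    n_extra = (1 if free_dd else 0) + (2 if maternal else 0)
    theta0 = np.zeros(2 + n_extra)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(neg, theta0, method="BFGS", options={"maxiter": 500})
    return -res.fun


def fit_poe(triads, *, snp_col: int = 0, **options) -> POEResults:
    """Functional front door: build a :class:`TriadPOEModel` and fit it."""
    fit_kw = {k: options.pop(k) for k in ("method", "maxiter", "n_starts", "start_params")
              if k in options}
    model = (TriadPOEModel(triads, **options) if isinstance(triads, np.ndarray)
             else TriadPOEModel.from_triads(triads, snp_col=snp_col, **options))
    return model.fit(**fit_kw)


def classify_transmission(triads, risk_allele: str = A2, snp_col: int = 0
                          ) -> tuple[int, int, int]:
    """Tally which parent contributed the risk allele among case children.

    Children whose heterozygous origin is determinable (exactly one origin
    configuration) add to the contributing parent's tally; risk-homozygous
    children add to both tallies once each; all-heterozygous (ambiguous) trios
    are counted separately. Returns (n_paternal, n_maternal, n_ambiguous).
    """
    if risk_allele not in (A1, A2):
        raise ValueError("risk_allele must be 'a1' or 'a2'")
    arr = triads if isinstance(triads, np.ndarray) else triads_to_array(triads, snp_col)
    n_pat = n_mat = n_amb = 0
    for gm, gf, gc in arr:
        if MISSING in (gm, gf, gc):
            continue
        configs = enumerate_origins(int(gm), int(gf), int(gc))
        if not configs:
            continue
        if len(configs) > 1:
            n_amb += 1
            continue
        c = configs[0]
        if c.c_m == risk_allele:
            n_mat += 1
        if c.c_f == risk_allele:
            n_pat += 1
    return n_pat, n_mat, n_amb
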