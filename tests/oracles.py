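"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (enumeration, exact
arithmetic, grid search) and deliberately shares no code with the package's
computation paths.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def hwe_enumeration_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact HWE test p-value by full enumeration with rational arithmetic."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het  # allele-1 count
    probs: dict[int, Fraction] = {}
    total = Fraction(0)
    for het in range(n + 1):
        h1_twice = n_a - het
        if h1_twice < 0 or h1_twice % 2:
            continue
        h1 = h1_twice // 2
        h2 = n - h1 - het
        if h2 < 0:
            continue
        # multinomial genotype count x 2^het arrangements of het alleles
        w = Fraction(math.factorial(n),
                     math.factorial(h1) * math.factorial(het) * math.factorial(h2)
                     ) * Fraction(2) ** het
        probs[het] = w
        total += w
    p_obs = probs[n_het] / total
    return float(sum(w for w in probs.values() if w / total <= p_obs) / total)


def bh_stepup(pvals: np.ndarray) -> np.ndarray:
    """Literal step-up BH definition: adj_(i) = min_{j>=i} min(1, m p_(j)/j)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, min(1.0, m * p[order[rank - 1]] / rank))
        adj_sorted[rank - 1] = running
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _penetrance(cm: int, cf: int, g_m: int, rr_m, rr_f, rr_dd, mat1, mat2) -> float:
    val = (rr_m if cm else 1.0) * (rr_f if cf else 1.0)
    if cm and cf:
        val *= rr_dd
    if g_m == 1:
        val *= mat1
    elif g_m == 2:
        val *= mat2
    return val


def _hwe_prob(g: int, q: float) -> float:
    return [(1 - q) ** 2, 2 * q * (1 - q), q * q][g]


def _transmissions(g: int):
    if g == 0:
        return [(0, 1.0)]
    if g == 2:
        return [(1, 1.0)]
    return [(0, 0.5), (1, 0.5)]


def triad_loglik_bruteforce(triples, q, rr_m, rr_f, rr_dd=1.0, mat1=1.0, mat2=1.0,
                            missing=-1, baseline=1.0) -> float:
    """Enumerate every (g_M, g_F, c_m, c_f) combination per triad by brute force.

    Mirrors the model definition directly: conditional probability of the
    observed pattern given an affected child, with the normalizer computed by
    the same full enumeration. Missing single members are summed out.
    """
    z = 0.0
    for g_m, g_f in itertools.product(range(3), repeat=2):
        for cm, wm in _transmissions(g_m):
            for cf, wf in _transmissions(g_f):
                z += (_hwe_prob(g_m, q) * _hwe_prob(g_f, q) * wm * wf * baseline
                      * _penetrance(cm, cf, g_m, rr_m, rr_f, rr_dd, mat1, mat2))
    ll = 0.0
    for obs_m, obs_f, obs_c in np.asarray(triples, dtype=int):
        n_miss = sum(v == missing for v in (obs_m, obs_f, obs_c))
        if n_miss >= 2:
            continue
        num = 0.0
        for g_m, g_f in itertools.product(range(3), repeat=2):
            if obs_m != missing and g_m != obs_m:
                continue
            if obs_f != missing and g_f != obs_f:
                continue
            for cm, wm in _transmissions(g_m):
                for cf, wf in _transmissions(g_f):
                    if obs_c != missing and cm + cf != obs_c:
                        continue
                    num += (_hwe_prob(g_m, q) * _hwe_prob(g_f, q) * wm * wf * baseline
                            * _penetrance(cm, cf, g_m, rr_m, rr_f, rr_dd, mat1, mat2))
        if num == 0.0:  # Mendelian-inconsistent: excluded
            continue
        ll += math.log(num / z)
    return ll


def grid_search_mle(triples, *, resolution=1e-3, loglik=None):
    """Refining exhaustive grid search for the MLE of (q, rr_m, rr_f) with the
    double-dose deviation fixed at 1.

    The search covers q in (0,1) and log rr in [-3, 3], halving the span
    around the running optimum until the step is below ``resolution`` on each
    axis (absolute in q, relative in the RRs). ``loglik`` defaults to the
    brute-force enumeration above.
    """
    if loglik is None:
        # collapse to unique observation patterns for speed; the arithmetic
        # per pattern is still the full brute-force enumeration
        arr = np.asarray(triples, dtype=int)
        patterns, counts = np.unique(arr, axis=0, return_counts=True)

        def loglik(q, rm, rf):
            per = [triad_loglik_bruteforce([pat], q, rm, rf) for pat in patterns]
            return float(np.dot(counts, per))

    q_lo, q_hi = 0.02, 0.98
    lm_lo = lf_lo = -3.0
    lm_hi = lf_hi = 3.0
    npts = 13
    best = None
    while True:
        qs = np.linspace(q_lo, q_hi, npts)
        lms = np.linspace(lm_lo, lm_hi, npts)
        lfs = np.linspace(lf_lo, lf_hi, npts)
        best_val = -np.inf
        for q in qs:
            for lm in lms:
                for lf in lfs:
                    val = loglik(q, math.exp(lm), math.exp(lf))
                    if val > best_val:
                        best_val, best = val, (q, lm, lf)
        q0, lm0, lf0 = best
        q_step = (q_hi - q_lo) / (npts - 1)
        l_step = (lm_hi - lm_lo) / (npts - 1)
        if q_step < resolution and l_step < resolution:
            return {"q": q0, "rr_m": math.exp(lm0), "rr_f": math.exp(lf0),
                    "loglik": best_val, "q_step": q_step, "log_step": l_step}
        q_lo = max(0.005, q0 - 2 * q_step)
        q_hi = min(0.995, q0 + 2 * q_step)
        lm_lo, lm_hi = lm0 - 2 * l_step, lm0 + 2 * l_step
        lf_lo, lf_hi = lf0 - 2 * l_step, lf0 + 2 * l_step
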