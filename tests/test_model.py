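"""The triad likelihood, its MLE, and the latent-origin bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triadpoe as tp
from triadpoe.model import (
    MENDELIAN_TRIPLES,
    TriadPOEModel,
    conditional_triple_probs,
    triads_to_array,
)
from triadpoe.simulate import genotype_triples

from oracles import grid_search_mle, triad_loglik_bruteforce


# ---------------------------------------------------------------------------
# origin enumeration and penetrance
# ---------------------------------------------------------------------------

def test_het_mother_hom_father_origin_is_forced_maternal():
    (cfg,) = tp.enumerate_origins(1, 0, 1)
    assert (cfg.c_m, cfg.c_f, cfg.prior_weight) == ("a2", "a1", 0.5)


def test_all_het_trio_is_the_ambiguous_case():
    cfgs = tp.enumerate_origins(1, 1, 1)
    assert {(c.c_m, c.c_f) for c in cfgs} == {("a2", "a1"), ("a1", "a2")}
    assert all(c.prior_weight == 0.25 for c in cfgs)


def test_double_homozygote_origin_forced():
    (cfg,) = tp.enumerate_origins(2, 2, 2)
    assert (cfg.c_m, cfg.c_f, cfg.prior_weight) == ("a2", "a2", 1.0)


def test_inconsistent_trio_gives_empty_origin_list():
    assert tp.enumerate_origins(0, 0, 1) == []
    assert tp.enumerate_origins(0, 2, 0) == []


def test_origin_weights_multiply_mendelian_probabilities():
    for gm in range(3):
        for gf in range(3):
            total = sum(c.prior_weight
                        for gc in range(3) for c in tp.enumerate_origins(gm, gf, gc))
            assert total == pytest.approx(1.0)
            for gc in range(3):
                for c in tp.enumerate_origins(gm, gf, gc):
                    assert c.prior_weight in (1.0, 0.5, 0.25)


@pytest.mark.parametrize("cm,cf,gm,params,expected", [
    ("a1", "a1", 0, dict(rr_m=9, rr_f=9, rr_dd=9), 1.0),
    ("a2", "a1", 1, dict(rr_m=2), 2.0),
    ("a2", "a2", 2, dict(rr_m=2, rr_f=3, rr_dd=0.5), 3.0),
    ("a1", "a2", 0, dict(rr_f=4), 4.0),
])
def test_penetrance_factor_table(cm, cf, gm, params, expected):
    p = tp.POEParams(q=0.3, **params)
    cfg = tp.OriginConfig(cm, cf, 1.0)
    assert tp.penetrance_factor(cfg, gm, p) == pytest.approx(expected)


def test_penetrance_with_maternal_effects():
    p = tp.POEParams(q=0.3, rr_m=2, mat1=1.5, mat2=4.0)
    cfg = tp.OriginConfig("a2", "a1", 0.5)
    assert tp.penetrance_factor(cfg, 1, p) == pytest.approx(2 * 1.5)
    assert tp.penetrance_factor(cfg, 2, p) == pytest.approx(2 * 4.0)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def test_null_params_reduce_to_mendelian_hwe_prior():
    # with all RR = 1 the penetrance cancels: trio probabilities are the plain
    # HWE/Mendelian probabilities and (1,1,1) has mass 2q^2(1-q)^2 * 1/2 * ...
    q = 0.3
    probs = conditional_triple_probs(tp.POEParams(q=q))
    hwe = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    # P(M=1,F=1,C=1) = hwe1*hwe1*1/2 under the null
    assert probs[1, 1, 1] == pytest.approx(hwe[1] * hwe[1] * 0.5, abs=1e-12)
    assert probs[0, 0, 0] == pytest.approx(hwe[0] ** 2, abs=1e-12)


@given(st.floats(0.05, 0.95), st.floats(0.2, 5), st.floats(0.2, 5),
       st.floats(0.2, 5), st.floats(0.2, 5), st.floats(0.2, 5))
@settings(max_examples=50, deadline=None)
def test_conditional_probs_normalize_over_mendelian_triples(q, rm, rf, rdd, m1, m2):
    probs = conditional_triple_probs(
        tp.POEParams(q=q, rr_m=rm, rr_f=rf, rr_dd=rdd, mat1=m1, mat2=m2))
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    mass_on_mendelian = sum(probs[t] for t in MENDELIAN_TRIPLES)
    assert mass_on_mendelian == pytest.approx(1.0, abs=1e-12)
    assert len(MENDELIAN_TRIPLES) == 15


def test_loglik_matches_bruteforce_enumeration(fixed_200_triples):
    params = tp.POEParams(q=0.3, rr_m=2.0, rr_f=1.0, rr_dd=1.0)
    ours = tp.triad_loglik(fixed_200_triples[:20], params)
    oracle = triad_loglik_bruteforce(fixed_200_triples[:20], 0.3, 2.0, 1.0)
    assert ours == pytest.approx(oracle, abs=1e-10)


def test_loglik_with_missing_members_matches_bruteforce(fixed_200_triples):
    arr = fixed_200_triples[:30].copy()
    arr[0, 0] = -1   # missing mother
    arr[1, 1] = -1   # missing father
    arr[2, 2] = -1   # missing child
    arr[3, :2] = -1  # two missing -> dropped by both routes
    params = tp.POEParams(q=0.25, rr_m=1.7, rr_f=0.8, rr_dd=1.3, mat1=1.2, mat2=0.9)
    ours = tp.triad_loglik(arr, params)
    oracle = triad_loglik_bruteforce(arr, 0.25, 1.7, 0.8, 1.3, 1.2, 0.9)
    assert ours == pytest.approx(oracle, abs=1e-10)


def test_loglik_invariant_to_baseline_scaling(fixed_200_triples):
    """Multiplying every penetrance factor by a constant baseline B leaves the
    ascertainment-conditional log-likelihood unchanged, which is why B is not
    a model parameter."""
    params = tp.POEParams(q=0.3, rr_m=2.0, rr_f=0.5, rr_dd=1.4)
    ours = tp.triad_loglik(fixed_200_triples, params)
    for b in (1.0, 0.01, 3.7):
        perturbed = triad_loglik_bruteforce(fixed_200_triples, 0.3, 2.0, 0.5, 1.4,
                                            baseline=b)
        assert ours == pytest.approx(perturbed, abs=1e-10)


def test_label_symmetry_of_maximized_loglik(fixed_200_triples):
    """Swapping allele labels a1<->a2 relabels the data (g -> 2-g); the
    maximized log-likelihood must be unchanged."""
    m1 = TriadPOEModel(fixed_200_triples, free_rr_dd=True)
    swapped = np.where(fixed_200_triples >= 0, 2 - fixed_200_triples, -1)
    m2 = TriadPOEModel(swapped, free_rr_dd=True)
    f1, f2 = m1.fit(), m2.fit()
    assert f1.llf == pytest.approx(f2.llf, abs=1e-5)
    # and the fitted parameters map as q -> 1-q, rr -> 1/rr (up to rr_dd)
    assert f2.params.q == pytest.approx(1 - f1.params.q, abs=1e-3)


def test_no_informative_triads_raises():
    with pytest.raises(ValueError, match="informative"):
        tp.triad_loglik(np.full((5, 3), -1), tp.POEParams(q=0.3))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_mle_matches_grid_search_small_fixture(fixed_200_triples):
    fit = TriadPOEModel(fixed_200_triples[:80], free_rr_dd=False).fit()
    oracle = grid_search_mle(fixed_200_triples[:80], resolution=2e-3)
    assert fit.params.q == pytest.approx(oracle["q"], abs=5e-3)
    assert np.log(fit.params.rr_m) == pytest.approx(np.log(oracle["rr_m"]), abs=5e-3)
    assert np.log(fit.params.rr_f) == pytest.approx(np.log(oracle["rr_f"]), abs=5e-3)
    assert fit.llf >= oracle["loglik"] - 1e-6


def test_em_and_bfgs_reach_the_same_maximum(fixed_200_triples):
    model = TriadPOEModel(fixed_200_triples)
    direct = model.fit(method="bfgs")
    em = model.fit(method="em")
    assert em.llf == pytest.approx(direct.llf, abs=1e-4)
    assert em.params.rr_m == pytest.approx(direct.params.rr_m, rel=1e-2)


def test_recovery_ci_contains_truth_large_n():
    ds, _, _ = tp.simulate_triads(
        tp.SimConfig(n_triads=5000, q=0.3, baseline_b=0.05, rr_m=2.0, seed=55))
    fit = TriadPOEModel(genotype_triples(ds)).fit()
    lo, hi = fit.ratio_ci()
    assert lo < 2.0 < hi
    assert fit.converged


def test_min_informative_triads_guard():
    arr = np.tile([1, 0, 1], (5, 1))
    with pytest.raises(ValueError, match="informative"):
        TriadPOEModel(arr, min_informative_triads=10)


def test_monomorphic_snp_flagged_singular():
    arr = np.zeros((50, 3), dtype=int)
    fit = TriadPOEModel(arr).fit()
    assert fit.singular or not np.isfinite(fit.log_ratio_se)
    assert fit.ratio_ci() == (pytest.approx(np.nan, nan_ok=True),) * 2


def test_summary_mentions_ratio_and_ci(maternal_study):
    dataset, covariates, _ = maternal_study
    triads = tp.assemble_triads(dataset, covariates)
    fit = tp.fit_poe(triads)
    text = fit.summary()
    assert "RRm/RRf" in text and "95% CI" in text
    row = fit.to_row()
    assert set(row) >= {"n_triads", "ratio", "ci_low", "ci_high", "p_poe", "converged"}


def test_lrt_agrees_in_order_of_magnitude(maternal_study):
    dataset, covariates, _ = maternal_study
    triads = tp.assemble_triads(dataset, covariates)
    fit = tp.fit_poe(triads)
    p_wald, p_lrt = fit.p_poe, fit.p_poe_lrt()
    assert (p_wald < 0.05) == (p_lrt < 0.05)


# ---------------------------------------------------------------------------
# transmission classification
# ---------------------------------------------------------------------------

def test_classify_transmission_base_cases():
    assert tp.classify_transmission(np.array([[1, 0, 1]])) == (0, 1, 0)
    assert tp.classify_transmission(np.array([[1, 1, 1]])) == (0, 0, 1)
    assert tp.classify_transmission(np.array([[0, 1, 1]])) == (1, 0, 0)
    # risk-homozygous child contributes to both tallies once each
    assert tp.classify_transmission(np.array([[2, 2, 2]])) == (1, 1, 0)
    # hom-reference child carries no risk allele
    assert tp.classify_transmission(np.array([[0, 0, 0]])) == (0, 0, 0)


def test_classify_transmission_risk_allele_a1():
    assert tp.classify_transmission(np.array([[1, 2, 1]]), risk_allele="a1") == (0, 1, 0)
    assert tp.classify_transmission(np.array([[0, 0, 0]]), risk_allele="a1") == (1, 1, 0)


def test_maternal_effect_skews_transmission_direction():
    ds, _, _ = tp.simulate_triads(
        tp.SimConfig(n_triads=5000, q=0.3, baseline_b=0.02, rr_m=4.67, rr_f=1.0, seed=9))
    n_pat, n_mat, n_amb = tp.classify_transmission(genotype_triples(ds))
    assert n_mat > n_pat
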