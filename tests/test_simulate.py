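"""The synthetic triad generator: reproducibility, latent-truth consistency,
ascertainment behavior, and the fixture registry."""

import json

import numpy as np
import pytest
from scipy import stats

import triadpoe as tp
from triadpoe.io import MISSING
from triadpoe.simulate import FIXTURES, genotype_triples, make_fixture


def test_same_seed_identical_output():
    cfg = tp.SimConfig(n_triads=100, rr_m=2.0, missing_rate=0.05,
                       mendel_error_rate=0.02, n_snps=3, seed=5)
    a = tp.simulate_triads(cfg)
    b = tp.simulate_triads(cfg)
    assert np.array_equal(a[0].genotypes, b[0].genotypes)
    assert a[1].equals(b[1])
    assert a[2]["latent_transmissions"] == b[2]["latent_transmissions"]


def test_truth_record_reproduces_pristine_child_genotypes():
    cfg = tp.SimConfig(n_triads=150, rr_m=2.0, missing_rate=0.1,
                       mendel_error_rate=0.05, n_snps=2, seed=8)
    dataset, _, truth = tp.simulate_triads(cfg)
    pristine = np.array(truth["pristine_genotypes"], dtype=int)
    cm = np.array(truth["latent_transmissions"]["causal"]["c_m"])
    cf = np.array(truth["latent_transmissions"]["causal"]["c_f"])
    assert np.array_equal(pristine[2::3, cfg.causal_snp], cm + cf)
    for j_str, tr in truth["latent_transmissions"]["null"].items():
        j = int(j_str)
        assert np.array_equal(pristine[2::3, j],
                              np.array(tr["c_m"]) + np.array(tr["c_f"]))


def test_degenerate_frequency_rejected():
    with pytest.raises(ValueError, match="q"):
        tp.SimConfig(q=0.0)


def test_penetrance_bound_validated():
    with pytest.raises(ValueError, match="penetrance"):
        tp.SimConfig(baseline_b=0.5, rr_m=3.0)


def test_null_ascertainment_leaves_distribution_unchanged():
    """With all RR = 1 the acceptance probability is constant, so retained
    trios match the plain HWE/Mendelian law: parental allele frequency ~ q and
    child genotypes at their unascertained expectation."""
    q = 0.3
    ds, _, _ = tp.simulate_triads(tp.SimConfig(n_triads=4000, q=q, seed=21))
    arr = genotype_triples(ds)
    parents = np.concatenate([arr[:, 0], arr[:, 1]])
    freq = parents.sum() / (2 * parents.size)
    se = np.sqrt(q * (1 - q) / (2 * parents.size))
    assert abs(freq - q) < 5 * se
    # child genotype distribution: HWE(q) marginally
    expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * len(arr)
    observed = np.bincount(arr[:, 2], minlength=3)
    assert stats.chisquare(observed, expected).pvalue > 1e-4


def test_maternal_effect_biases_transmissions():
    ds, _, truth = tp.simulate_triads(
        tp.SimConfig(n_triads=5000, q=0.3, baseline_b=0.05, rr_m=2.0, rr_f=1.0, seed=23))
    cm = np.array(truth["latent_transmissions"]["causal"]["c_m"])
    cf = np.array(truth["latent_transmissions"]["causal"]["c_f"])
    # among children with exactly one risk transmission, maternal origin
    # dominates; binomial test against 1/2
    one = cm + cf == 1
    k, n = int(cm[one].sum()), int(one.sum())
    assert stats.binomtest(k, n, 0.5, alternative="greater").pvalue < 1e-6


def test_missingness_rate_close_to_nominal():
    ds, _, _ = tp.simulate_triads(
        tp.SimConfig(n_triads=1000, missing_rate=0.10, n_snps=4, seed=31))
    rate = (ds.genotypes == MISSING).mean()
    assert rate == pytest.approx(0.10, abs=0.01)


def test_injected_mendel_errors_are_real_violations():
    ds, _, truth = tp.simulate_triads(
        tp.SimConfig(n_triads=500, mendel_error_rate=0.2, seed=33))
    errors = truth["mendel_errors_injected"]
    assert len(errors) > 50
    g = ds.genotypes
    for e in errors[:50]:
        i, j = e["triad"], e["snp"]
        trio = (int(g[3 * i, j]), int(g[3 * i + 1, j]), int(g[3 * i + 2, j]))
        if MISSING not in trio:
            assert not tp.mendel_check(*trio)


def test_stratified_generation_labels_match_covariates():
    ds, cov, truth = tp.simulate_triads(tp.SimConfig(
        q=0.3, baseline_b=0.03, stratum_var="bmi_class",
        strata={">=28": tp.StratumSpec(100, rr_m=4.0),
                "<28": tp.StratumSpec(150)}, seed=41))
    labels = np.array(truth["stratum_labels"])
    derived = np.where(cov["bmi"].to_numpy() >= 28, ">=28", "<28")
    assert np.array_equal(labels, derived)
    assert (labels == ">=28").sum() == 100


def test_unreachable_ascertainment_errors():
    cfg = tp.SimConfig(n_triads=10, q=0.001, baseline_b=1e-9, seed=1)
    with pytest.raises(RuntimeError, match="ascertainment"):
        import triadpoe.simulate as sim
        old = sim._MAX_PROPOSALS
        sim._MAX_PROPOSALS = 50_000
        try:
            tp.simulate_triads(cfg)
        finally:
            sim._MAX_PROPOSALS = old


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def test_unknown_fixture_name_rejected(tmp_path):
    with pytest.raises(ValueError, match="unknown fixture"):
        make_fixture("nope", tmp_path)


def test_clean_null_fixture_ci_contains_one(tmp_path):
    make_fixture("clean_null", tmp_path)
    ds = tp.read_plink(tmp_path / "clean_null")
    cov = tp.read_covariates(tmp_path / "clean_null.cov.tsv")
    triads = tp.assemble_triads(ds, cov)
    assert len(triads) == FIXTURES["clean_null"].n_triads
    fit = tp.fit_poe(triads, snp_col=FIXTURES["clean_null"].causal_snp)
    lo, hi = fit.ratio_ci()
    assert lo < 1.0 < hi


def test_bmi_interaction_fixture_detects_interaction(tmp_path):
    make_fixture("bmi_interaction", tmp_path)
    ds = tp.read_plink(tmp_path / "bmi_interaction")
    cov = tp.read_covariates(tmp_path / "bmi_interaction.cov.tsv")
    triads = tp.assemble_triads(ds, cov)
    res = tp.fit_stratified(triads, "bmi_class")
    assert res.p_interaction < 0.05
    assert res.fits[">=28"].ratio > res.fits["<28"].ratio


def test_fixture_truth_json_written(tmp_path):
    make_fixture("strong_maternal", tmp_path)
    truth = json.loads((tmp_path / "strong_maternal.truth.json").read_text())
    assert truth["config"]["rr_m"] == 4.0
    assert "pristine_genotypes" not in truth
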