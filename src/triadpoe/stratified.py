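"""Stratified parent-of-origin fits and POE-by-environment interaction tests.

Triads are split by an offspring covariate (smoking, drinking, the obesity
class at the 28 kg/m^2 BMI cut, or sex for the sensitivity analysis), the POE
model is fitted within each stratum and overall, and heterogeneity of the log
POE ratio across strata is tested with a Wald contrast: for two strata

    z = (theta_A - theta_B) / sqrt(se_A^2 + se_B^2),   theta = log(rr_m/rr_f),

two-sided normal p; for more strata an inverse-variance-weighted chi-square
heterogeneity statistic with strata-1 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import Triad
from .model import POEResults, TriadPOEModel, triads_to_array

__all__ = ["StratifiedPOEResults", "fit_stratified", "interaction_test"]


@dataclass
class StratifiedPOEResults:
    """Per-stratum POE fits plus the overall fit and the interaction test."""

    stratum_var: str
    fits: dict[str, POEResults | None]
    overall: POEResults
    interaction_z: float | None = None
    p_interaction: float | None = None
    unfit_strata: list[str] = field(default_factory=list)
    n_missing_stratum: int = 0

    def summary(self) -> str:
        lines = [f"POE stratified by {self.stratum_var}", "=" * 60]
        for label, fit in self.fits.items():
            if fit is None:
                lines.append(f"  {label:>8}: too few informative triads (unfit)")
            else:
                lo, hi = fit.ratio_ci()
                lines.append(
                    f"  {label:>8}: RRm/RRf = {fit.ratio:.3f} "
                    f"({lo:.3f} - {hi:.3f}), P = {fit.p_poe:.3g}, "
                    f"n = {fit.n_triads_used}")
        lo, hi = self.overall.ratio_ci()
        lines.append(
            f"  {'overall':>8}: RRm/RRf = {self.overall.ratio:.3f} "
            f"({lo:.3f} - {hi:.3f}), P = {self.overall.p_poe:.3g}")
        if self.p_interaction is not None:
            lines.append(f"P_interaction = {self.p_interaction:.3g}")
        else:
            lines.append("P_interaction not computed")
        return "\n".join(lines)

    def to_rows(self, rsid: str = "") -> list[dict]:
        rows = []
        for label, fit in {**self.fits, "overall": self.overall}.items():
            if fit is None:
                rows.append({"rsid": rsid, "stratum": label, "ratio": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "p_stratum": np.nan, "p_interaction": self.p_interaction})
            else:
                lo, hi = fit.ratio_ci()
                rows.append({"rsid": rsid, "stratum": label, "ratio": fit.ratio,
                             "ci_low": lo, "ci_high": hi, "p_stratum": fit.p_poe,
                             "p_interaction": self.p_interaction})
        return rows


def interaction_test(fit_a: POEResults, fit_b: POEResults) -> tuple[float, float]:
    """Two-stratum Wald contrast on the log POE ratio.

    Returns (z, two-sided p). Antisymmetric in its arguments.
    """
    for f in (fit_a, fit_b):
        if not f.converged or not np.isfinite(f.log_ratio_se):
            raise ValueError("interaction test needs converged fits with finite SEs")
    z = (fit_a.log_ratio - fit_b.log_ratio) / np.hypot(fit_a.log_ratio_se,
                                                       fit_b.log_ratio_se)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def _heterogeneity_chi2(fits: list[POEResults]) -> tuple[float, float]:
    """Inverse-variance-weighted heterogeneity chi-square, df = k-1."""
    theta = np.array([f.log_ratio for f in fits])
    w = np.array([1.0 / f.log_ratio_se ** 2 for f in fits])
    mean = (w * theta).sum() / w.sum()
    q = float((w * (theta - mean) ** 2).sum())
    df = len(fits) - 1
    return q, float(stats.chi2.sf(q, df))


def fit_stratified(triads: list[Triad], stratum_var: str, *, snp_col: int = 0,
                   method: str = "bfgs", lrt: bool = False,
                   **model_options) -> StratifiedPOEResults:
    """Fit the POE model per stratum of an offspring covariate and test
    interaction.

    Triads with a missing stratum value enter the overall fit only. A stratum
    below the model's minimum informative-triad count is reported unfit and
    the interaction is not computed. ``lrt=True`` replaces the Wald contrast
    with a full-homogeneity likelihood-ratio test (all stratum parameters
    common vs free).
    """
    by_stratum: dict[str, list[Triad]] = {}
    n_missing = 0
    for t in triads:
        if t.covariates_missing:
            n_missing += 1
            continue
        label = t.stratum_value(stratum_var)
        if label is None:
            n_missing += 1
            continue
        by_stratum.setdefault(str(label), []).append(t)
    if not by_stratum:
        raise ValueError(f"stratum variable {stratum_var!r} is missing for every triad")

    overall_model = TriadPOEModel.from_triads(triads, snp_col=snp_col, **model_options)
    overall = overall_model.fit(method=method)

    fits: dict[str, POEResults | None] = {}
    unfit: list[str] = []
    for label in sorted(by_stratum):
        try:
            m = TriadPOEModel.from_triads(by_stratum[label], snp_col=snp_col,
                                          **model_options)
            fits[label] = m.fit(method=method)
        except ValueError:
            fits[label] = None
            unfit.append(label)

    res = StratifiedPOEResults(stratum_var=stratum_var, fits=fits, overall=overall,
                               unfit_strata=unfit, n_missing_stratum=n_missing)
    good = [f for f in fits.values()
            if f is not None and f.converged and np.isfinite(f.log_ratio_se)]
    if len(good) == len(fits) and len(good) >= 2:
        if lrt:
            res.interaction_z, res.p_interaction = _homogeneity_lrt(
                by_stratum, snp_col, method, model_options)
        elif len(good) == 2:
            res.interaction_z, res.p_interaction = interaction_test(good[0], good[1])
        else:
            res.interaction_z, res.p_interaction = _heterogeneity_chi2(good)
    return res


def _homogeneity_lrt(by_stratum, snp_col, method, model_options) -> tuple[float, float]:
    """LRT of all parameters common across strata vs stratum-specific."""
    pooled_triples = np.concatenate(
        [triads_to_array(ts, snp_col) for ts in by_stratum.values()])
    pooled = TriadPOEModel(pooled_triples, **model_options).fit(method=method)
    ll_free = 0.0
    n_par = len(pooled.param_names)
    for ts in by_stratum.values():
        ll_free += TriadPOEModel.from_triads(ts, snp_col=snp_col,
                                             **model_options).fit(method=method).llf
    lr = max(0.0, 2 * (ll_free - pooled.llf))
    df = (len(by_stratum) - 1) * n_par
    return float(lr), float(stats.chi2.sf(lr, df))
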