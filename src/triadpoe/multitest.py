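"""Benjamini-Hochberg false-discovery-rate adjustment for per-SNP p-values."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust"]

logger = logging.getLogger(__name__)


def bh_adjust(pvals) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing (NaN) entries are excluded from the family size m and returned as
    NaN; adjusted values are capped at 1 (the pre-cap maximum is logged for
    transparency). Accepts a sequence, array or Series; returns the same
    positional order (and index, for a Series).
    """
    is_series = isinstance(pvals, pd.Series)
    arr = np.asarray(pd.Series(pvals).to_numpy(), dtype=float)
    obs = ~np.isnan(arr)
    if ((arr[obs] < 0) | (arr[obs] > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    adj = np.full_like(arr, np.nan)
    if obs.any():
        p = arr[obs]
        m = p.size
        order = np.argsort(p, kind="stable")
        ranked = p[order] * m / np.arange(1, m + 1)
        precap_max = float(ranked.max())
        if precap_max > 1:
            logger.info("BH: pre-cap adjusted p-values reach %.3g (capped at 1)", precap_max)
        adj[obs] = multipletests(p, method="fdr_bh")[1]
    if is_series:
        return pd.Series(adj, index=pvals.index)
    return adj
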