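"""Tumor-vs-normal differential analysis per omics layer.

Expression uses a moderated two-sample statistic with a permutation-based
false discovery rate and a fold-change filter (a documented stand-in for the
SAM workflow; the moderation constant s0 is the median per-gene pooled
standard error). Methylation uses the Mann-Whitney-Wilcoxon test with
Benjamini-Hochberg FDR at a stringent threshold (default 0.005).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["differential_expression", "differential_methylation"]


def _moderated_t(
    tumor: np.ndarray, normal: np.ndarray, s0: float | None = None
) -> tuple[np.ndarray, float]:
    nt, nn = tumor.shape[1], normal.shape[1]
    diff = tumor.mean(axis=1) - normal.mean(axis=1)
    pooled_var = (
        tumor.var(axis=1, ddof=1) * (nt - 1) + normal.var(axis=1, ddof=1) * (nn - 1)
    ) / (nt + nn - 2)
    se = np.sqrt(pooled_var * (1 / nt + 1 / nn))
    if s0 is None:
        s0 = float(np.median(se))
    return diff / (se + s0), s0


def differential_expression(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    n_perm: int = 200,
    rng: np.random.Generator | int | None = None,
    log2_input: bool = False,
) -> pd.DataFrame:
    """Differentially expressed genes by moderated statistic + permutation FDR.

    Per gene: a two-sample t-like statistic with variance-stabilizing constant
    s0; the q-value is a permutation FDR (group labels permuted ``n_perm``
    times, tail counts of the null statistic vs observed). Significance
    requires the fold change (linear-scale mean ratio, direction-aware) to
    reach ``fc_min`` and q < ``fdr_max``. With ``log2_input`` the fold-change
    criterion becomes |difference of means| >= log2(fc_min).
    """
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need >= 2 samples in each group")
    genes = tumor.index
    normal = normal.reindex(genes)
    t = tumor.to_numpy(dtype=float)
    n = normal.to_numpy(dtype=float)
    rng = np.random.default_rng(rng)

    d_obs, s0 = _moderated_t(t, n)

    combined = np.hstack([t, n])
    nt = t.shape[1]
    null_abs = np.empty((n_perm, len(genes)))
    for b in range(n_perm):
        perm = rng.permutation(combined.shape[1])
        d_perm, _ = _moderated_t(combined[:, perm[:nt]], combined[:, perm[nt:]], s0=s0)
        null_abs[b] = np.abs(d_perm)

    # permutation FDR at each gene's own |d| threshold, monotonized
    abs_obs = np.abs(d_obs)
    order = np.argsort(-abs_obs)
    null_sorted = np.sort(null_abs.ravel())
    q = np.empty(len(genes))
    n_null_total = null_sorted.size
    for rank, gi in enumerate(order, start=1):
        exceed_null = n_null_total - np.searchsorted(null_sorted, abs_obs[gi], side="left")
        expected_fp = exceed_null / n_perm
        q[gi] = min(1.0, expected_fp / rank)
    # enforce monotone non-increasing q along decreasing |d|
    running = 1.0
    for gi in order[::-1]:
        running = min(running, q[gi])
        q[gi] = running

    with np.errstate(divide="ignore", invalid="ignore"):
        if log2_input:
            fc = t.mean(axis=1) - n.mean(axis=1)
            passes_fc = np.abs(fc) >= np.log2(fc_min)
        else:
            mt, mn = t.mean(axis=1), n.mean(axis=1)
            fc = np.where(mn != 0, mt / mn, np.inf)
            passes_fc = (fc >= fc_min) | ((fc > 0) & (fc <= 1 / fc_min))
    pvals = 2 * stats.norm.sf(abs_obs)  # descriptive; q drives significance
    out = pd.DataFrame(
        {
            "gene": genes,
            "stat": d_obs,
            "fc": fc,
            "p": pvals,
            "q": q,
            "direction": np.where(d_obs >= 0, "up", "down"),
        }
    ).set_index("gene")
    out["significant"] = passes_fc & (out["q"] < fdr_max)
    return out


def differential_methylation(
    tumor: pd.DataFrame, normal: pd.DataFrame, fdr_max: float = 0.005
) -> pd.DataFrame:
    """Differentially methylated genes by Mann-Whitney U with BH FDR.

    Per gene a two-sided U test (exact at small sample sizes, otherwise the
    normal approximation with tie correction); direction hyper/hypo by the
    sign of the tumor-minus-normal median difference; significant <=>
    q < ``fdr_max``.
    """
    if tumor.shape[1] < 2 or normal.shape[1] < 2:
        raise ValueError("need >= 2 samples in each group")
    genes = tumor.index
    normal = normal.reindex(genes)
    t = tumor.to_numpy(dtype=float)
    n = normal.to_numpy(dtype=float)

    pvals = np.ones(len(genes))
    stats_u = np.zeros(len(genes))
    for i in range(len(genes)):
        if np.ptp(np.concatenate([t[i], n[i]])) == 0:
            stats_u[i] = t.shape[1] * n.shape[1] / 2
            pvals[i] = 1.0
            continue
        res = stats.mannwhitneyu(t[i], n[i], alternative="two-sided", method="auto")
        stats_u[i] = res.statistic
        pvals[i] = res.pvalue
    q = multipletests(pvals, method="fdr_bh")[1]
    med_diff = np.median(t, axis=1) - np.median(n, axis=1)
    out = pd.DataFrame(
        {
            "gene": genes,
            "stat": stats_u,
            "p": pvals,
            "q": q,
            "direction": np.where(med_diff >= 0, "hyper", "hypo"),
        }
    ).set_index("gene")
    out["significant"] = out["q"] < fdr_max
    return out
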