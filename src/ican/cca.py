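"""Canonical-correlation edge weighting of gene pairs.

Each gene carries a 3 x n profile over samples: expression, copy number and
promoter methylation. For a pair of genes with profiles G1, G2 the canonical
correlations rho_k are the square roots of the eigenvalues lambda_k of the
Rayleigh quotient matrix

    R = S11^{-1/2} S12 S22^{-1} S21 S11^{-1/2},

where S11, S12, S22 are the sample covariance blocks of the stacked 6-variate
profile. Bartlett's sequential chi-squared test screens the components, and
the edge weight omega averages lambda_k over the significant components with
weights -log p_k:

    omega = sum_k lambda_k * I(p_k) / sum_k I(p_k),
    I(p) = -log p if p <= 0.05 else 0,

so omega in [0, 1] measures how strongly the two genes co-alter across the
three molecular levels; omega = 0 when no component is significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairCCAResult",
    "pair_cca",
    "bartlett_pvalues",
    "edge_weight",
    "pearson_weight",
    "pair_cca_result",
]

_RIDGE = 1e-8
_ALPHA = 0.05


@dataclass
class PairCCAResult:
    """Full canonical-correlation summary for one gene pair."""

    lambdas: np.ndarray  # descending eigenvalues of R, in [0, 1]
    rhos: np.ndarray  # canonical correlations, sqrt(lambda)
    T: np.ndarray  # Bartlett statistics, one per sequential hypothesis
    pvals: np.ndarray
    omega: float
    n: int
    degenerate: bool = False  # ridge regularization engaged for a flat row


def _inv_sqrt_psd(a: np.ndarray) -> np.ndarray:
    """Inverse symmetric square root of a PSD matrix via eigendecomposition."""
    w, v = np.linalg.eigh(a)
    w = np.maximum(w, np.finfo(float).tiny)
    return (v / np.sqrt(w)) @ v.T


def pair_cca(G1: np.ndarray, G2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Canonical correlations between two p x n sample profiles.

    Returns ``(lambdas, rhos)`` with lambdas the descending eigenvalues of the
    Rayleigh quotient matrix (clipped to [0, 1]) and rhos their square roots.
    Covariance blocks use 1/(n-1); S11 and S22 receive a ridge of
    1e-8 * trace/p before inversion so that a constant row (e.g. a gene with
    flat copy number) degrades gracefully instead of failing. Raises
    ``ValueError`` when both profiles are entirely constant or n < 5.
    """
    G1 = np.asarray(G1, dtype=float)
    G2 = np.asarray(G2, dtype=float)
    if G1.ndim != 2 or G2.ndim != 2 or G1.shape[1] != G2.shape[1]:
        raise ValueError("G1 and G2 must be p x n over identical samples")
    n = G1.shape[1]
    if n < 5:
        raise ValueError(f"need at least 5 samples, got {n}")
    p = G1.shape[0]

    X = G1 - G1.mean(axis=1, keepdims=True)
    Y = G2 - G2.mean(axis=1, keepdims=True)
    if not (X.any() or Y.any()):
        raise ValueError("both profiles are constant; CCA undefined")
    s11 = X @ X.T / (n - 1)
    s22 = Y @ Y.T / (n - 1)
    s12 = X @ Y.T / (n - 1)
    # ridge only when a block is (near-)singular, e.g. a constant CN row;
    # well-conditioned pairs are computed exactly
    for name, s in (("s11", s11), ("s22", s22)):
        w = np.linalg.eigvalsh(s)
        if w[0] <= 1e-10 * max(w[-1], np.finfo(float).tiny):
            s += _RIDGE * max(np.trace(s) / p, np.finfo(float).tiny) * np.eye(p)

    s11_isqrt = _inv_sqrt_psd(s11)
    r = s11_isqrt @ s12 @ np.linalg.solve(s22, s12.T) @ s11_isqrt
    lambdas = np.linalg.eigvalsh((r + r.T) / 2)[::-1]
    lambdas = np.clip(lambdas, 0.0, 1.0)
    return lambdas, np.sqrt(lambdas)


def is_degenerate_pair(G1: np.ndarray, G2: np.ndarray) -> bool:
    """True when either profile contains a zero-variance row."""
    return any(
        np.ptp(np.asarray(G, dtype=float), axis=1).min() == 0.0 for G in (G1, G2)
    )


def bartlett_pvalues(
    lambdas: np.ndarray,
    n: int,
    p: int = 3,
    q: int | None = None,
    form: str = "printed",
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential Bartlett chi-squared tests on canonical correlations.

    Test k (k = 1..p) addresses H0: components k..p are all zero, with

        T_k = -[n - (p + q + 3)/2] * sum_{i=k..p} log(1 - lambda_i)

    referred to chi-squared on (p-k+1)(q-k+1) degrees of freedom. ``form``
    selects the multiplier: ``"printed"`` uses n - (p+q+3)/2 and
    ``"standard"`` uses n - 1 - (p+q+1)/2 — identical quantities, both kept
    for transparency. 1 - lambda is floored at 1e-12 before the log.
    """
    if q is None:
        q = p
    min_n = (p + q + 3) / 2
    if n <= min_n:
        raise ValueError(f"need n > {min_n}, got {n}")
    if form == "printed":
        coef = n - (p + q + 3) / 2
    elif form == "standard":
        coef = n - 1 - (p + q + 1) / 2
    else:
        raise ValueError("form must be 'printed' or 'standard'")
    lam = np.asarray(lambdas, dtype=float)
    log_terms = np.log(np.maximum(1.0 - lam, 1e-12))
    k = np.arange(1, p + 1)
    # T_k sums the tail i = k..p
    T = -coef * np.array([log_terms[k0 - 1 :].sum() for k0 in k])
    df = (p - k + 1) * (q - k + 1)
    pvals = stats.chi2.sf(T, df)
    return T, pvals


def edge_weight(
    lambdas: np.ndarray,
    pvals: np.ndarray,
    alpha: float = _ALPHA,
    weight_basis: str = "lambda",
) -> float:
    """Significance-weighted average of lambda_k over significant components.

    Components with p_k <= alpha contribute weight -log p_k; omega is 0 when
    no component is significant. ``weight_basis="rho"`` averages the canonical
    correlations instead of the eigenvalues.
    """
    lam = np.asarray(lambdas, dtype=float)
    pv = np.asarray(pvals, dtype=float)
    if lam.shape != pv.shape:
        raise ValueError("lambdas and pvals must have equal length")
    if weight_basis == "rho":
        values = np.sqrt(lam)
    elif weight_basis == "lambda":
        values = lam
    else:
        raise ValueError("weight_basis must be 'lambda' or 'rho'")
    w = np.where(pv <= alpha, -np.log(np.maximum(pv, 1e-300)), 0.0)
    denom = w.sum()
    if denom == 0.0:
        return 0.0
    return float(np.clip((values * w).sum() / denom, 0.0, 1.0))


def pearson_weight(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Absolute Pearson correlation as a single-layer edge weight.

    Returns ``(weight, signed_r)``; a zero-variance vector yields weight 0
    with signed_r = nan (flagged via the nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return abs(r), r


def pair_cca_result(
    G1: np.ndarray,
    G2: np.ndarray,
    alpha: float = _ALPHA,
    weight_basis: str = "lambda",
    bartlett_form: str = "printed",
) -> PairCCAResult:
    """End-to-end CCA weighting of one gene pair."""
    n = np.asarray(G1).shape[1]
    lambdas, rhos = pair_cca(G1, G2)
    T, pvals = bartlett_pvalues(lambdas, n=n, p=len(lambdas), form=bartlett_form)
    omega = edge_weight(lambdas, pvals, alpha=alpha, weight_basis=weight_basis)
    return PairCCAResult(
        lambdas=lambdas,
        rhos=rhos,
        T=T,
        pvals=pvals,
        omega=omega,
        n=n,
        degenerate=is_degenerate_pair(G1, G2),
    )
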