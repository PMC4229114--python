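"""Baseline network reconstruction from expression data.

Three estimators of a gene-gene association network, spanning the main
families used in co-expression / Gaussian-graphical-model inference:

``reconstruct_space``
    Sparse partial correlation by joint L1-penalised regression with a
    symmetry constraint (SPACE-style).  Every gene's standardised
    expression is regressed on all others simultaneously, with the
    regression coefficients tied through the partial-correlation
    parameterisation ``beta_ij = rho_ij * sqrt(d_j / d_i)`` (``d_i`` the
    diagonal of the concentration matrix), minimising

        1/2 * sum_i || y_i - sum_{j != i} beta_ij y_j ||^2
            + lambda * sum_{i<j} |rho_ij|

    by cyclic coordinate descent over the pairs.  The lasso penalty
    zeroes most pairs, so the output is a sparse signed partial
    correlation matrix.

``reconstruct_shrinkage_pcor``
    Dense partial correlations from a Schaefer-Strimmer-type shrinkage
    correlation estimate: the sample correlation matrix is shrunk toward
    the identity with the analytic data-driven intensity
    ``sum var(r_ij) / sum r_ij^2`` (clipped to [0, 1]), inverted
    (Moore-Penrose pseudoinverse when singular), and the negated scaled
    inverse gives partial correlations.  Scores are |pcor|.

``reconstruct_softcor``
    Weighted-correlation-network soft thresholding: the adjacency is
    |Pearson correlation| ** beta (default beta = 6).  Raising a power
    beta >= 1 preserves the edge ranking while de-emphasising weak
    correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.stats import norm

from .netio import ExpressionMatrix, ValidationError, WeightedNetwork

__all__ = [
    "ReconstructionConfig",
    "reconstruct",
    "reconstruct_space",
    "reconstruct_shrinkage_pcor",
    "reconstruct_softcor",
    "default_space_lambda",
    "shrinkage_intensity",
    "METHODS",
]

logger = logging.getLogger("ena.reconstruction")


@dataclass(frozen=True)
class ReconstructionConfig:
    """Tuning knobs shared by the reconstructors.

    ``lam`` applies to SPACE only ("auto" picks a Bonferroni-style
    default, see :func:`default_space_lambda`); ``beta`` applies to the
    soft-threshold method only; ``max_iter``/``tol`` bound the SPACE
    coordinate descent (max absolute change in any rho per sweep).
    """

    method: str = "space"
    lam: float | str = "auto"
    beta: float = 6.0
    max_iter: int = 500
    tol: float = 1e-6
    outer_iter: int = 3

    def __post_init__(self) -> None:
        if self.lam != "auto" and not (isinstance(self.lam, (int, float)) and self.lam > 0):
            raise ValidationError("lam must be 'auto' or a positive number")
        if self.beta < 1:
            raise ValidationError("beta must be >= 1")
        if self.tol <= 0 or self.max_iter <= 0:
            raise ValidationError("tol and max_iter must be positive")


def _check_input(expr: ExpressionMatrix, min_samples: int = 3) -> None:
    if expr.n_genes < 2:
        raise ValidationError("need at least 2 genes")
    if expr.n_samples < min_samples:
        raise ValidationError(f"need at least {min_samples} samples, got {expr.n_samples}")
    sd = expr.values.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [expr.gene_ids[i] for i in dead]
        raise ValidationError(f"zero-variance gene(s): {names}")


def _standardize(expr: ExpressionMatrix) -> np.ndarray:
    """Per-gene mean 0, variance 1 (population sd), so ||z_i||^2 = n."""
    x = expr.values
    z = x - x.mean(axis=1, keepdims=True)
    z /= z.std(axis=1, keepdims=True)
    return z


def default_space_lambda(n_samples: int, n_genes: int, alpha: float = 0.05) -> float:
    """Bonferroni-style default penalty: sqrt(n) * PHI^-1(1 - alpha/(2 p^2))."""
    return float(np.sqrt(n_samples) * norm.ppf(1.0 - alpha / (2.0 * n_genes**2)))


@njit(cache=True)
def _space_sweeps(S, d, rho, BS, lam, max_iter, tol):  # pragma: no cover - jitted
    p = S.shape[0]
    sweeps = 0
    for _ in range(max_iter):
        sweeps += 1
        delta = 0.0
        for i in range(p - 1):
            for j in range(i + 1, p):
                aij = np.sqrt(d[j] / d[i])
                aji = np.sqrt(d[i] / d[j])
                cur = rho[i, j]
                # residual inner products excluding this pair's own term
                riYj = S[i, j] - BS[i, j] + cur * aij * S[j, j]
                rjYi = S[i, j] - BS[j, i] + cur * aji * S[i, i]
                A = aij * aij * S[j, j] + aji * aji * S[i, i]
                C = aij * riYj + aji * rjYi
                if C > lam:
                    new = (C - lam) / A
                elif C < -lam:
                    new = (C + lam) / A
                else:
                    new = 0.0
                if new != cur:
                    diff = new - cur
                    for k in range(p):
                        BS[i, k] += diff * aij * S[j, k]
                        BS[j, k] += diff * aji * S[i, k]
                    rho[i, j] = new
                    rho[j, i] = new
                    ad = abs(diff)
                    if ad > delta:
                        delta = ad
        if delta < tol:
            return sweeps, True
    return sweeps, False


def _space_bs(S: np.ndarray, rho: np.ndarray, d: np.ndarray) -> np.ndarray:
    """B @ S for the current (rho, d), with B_ij = rho_ij sqrt(d_j/d_i)."""
    B = rho * np.sqrt(d[None, :] / d[:, None])
    return B @ S


def reconstruct_space(
    expr: ExpressionMatrix, config: ReconstructionConfig | None = None
) -> WeightedNetwork:
    """SPACE-style sparse symmetric partial-correlation network.

    Returns signed partial-correlation estimates; most off-diagonal
    entries are exactly zero at the default penalty.
    """
    config = config or ReconstructionConfig(method="space")
    _check_input(expr)
    z = _standardize(expr)
    p, n = z.shape
    S = z @ z.T
    lam = default_space_lambda(n, p) if config.lam == "auto" else float(config.lam)

    rho = np.zeros((p, p))
    d = np.ones(p)
    converged = True
    sweeps_total = 0
    for outer in range(config.outer_iter):
        BS = _space_bs(S, rho, d)
        sweeps, ok = _space_sweeps(S, d, rho, BS, lam, config.max_iter, config.tol)
        sweeps_total += sweeps
        converged = converged and ok
        # refresh the concentration diagonal from residual variances
        B = rho * np.sqrt(d[None, :] / d[:, None])
        BSm = B @ S
        rss = np.diag(S) - 2 * np.diag(BSm) + np.sum(B * BSm, axis=1)
        rss = np.maximum(rss, 1e-12)
        d_new = n / rss
        if outer < config.outer_iter - 1 and np.max(np.abs(d_new - d)) < config.tol:
            d = d_new
            break
        d = d_new
    if not converged:
        warnings.warn(
            f"SPACE coordinate descent did not converge in {config.max_iter} sweeps; "
            "returning the partial fit",
            RuntimeWarning,
            stacklevel=2,
        )
    logger.info(
        "space: p=%d n=%d lambda=%.4g sweeps=%d nonzero=%d",
        p, n, lam, sweeps_total, int(np.count_nonzero(np.triu(rho, 1))),
    )
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 0.0)
    return WeightedNetwork(expr.gene_ids, (rho + rho.T) / 2.0)


def shrinkage_intensity(expr: ExpressionMatrix) -> float:
    """Analytic shrinkage intensity toward the identity correlation
    target: sum of estimated variances of the sample correlations over
    the sum of their squares, clipped to [0, 1]."""
    _check_input(expr)
    x = expr.values
    n = expr.n_samples
    xc = x - x.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1, ddof=1, keepdims=True)
    z = xc / sd
    r = (z @ z.T) / (n - 1)
    w_bar = (z @ z.T) / n
    w2_sum = (z**2) @ (z**2).T
    var_r = n / (n - 1.0) ** 3 * (w2_sum - n * w_bar**2)
    mask = ~np.eye(expr.n_genes, dtype=bool)
    denom = np.sum(r[mask] ** 2)
    if denom == 0:
        return 1.0
    return float(np.clip(np.sum(var_r[mask]) / denom, 0.0, 1.0))


def reconstruct_shrinkage_pcor(
    expr: ExpressionMatrix, config: ReconstructionConfig | None = None
) -> WeightedNetwork:
    """Dense |partial correlation| network from the shrinkage
    correlation estimate (pseudoinverse-based)."""
    _check_input(expr)
    n = expr.n_samples
    x = expr.values
    xc = x - x.mean(axis=1, keepdims=True)
    z = xc / xc.std(axis=1, ddof=1, keepdims=True)
    r = (z @ z.T) / (n - 1)
    np.fill_diagonal(r, 1.0)
    lam = shrinkage_intensity(expr)
    logger.info("shrinkage_pcor: p=%d n=%d intensity=%.4f", expr.n_genes, n, lam)
    r_shrunk = (1.0 - lam) * r
    np.fill_diagonal(r_shrunk, 1.0)
    conc = np.linalg.pinv(r_shrunk, hermitian=True)
    dd = np.sqrt(np.abs(np.diag(conc)))
    dd[dd == 0] = 1.0
    pcor = -conc / np.outer(dd, dd)
    np.fill_diagonal(pcor, 0.0)
    scores = np.abs((pcor + pcor.T) / 2.0)
    return WeightedNetwork(expr.gene_ids, scores)


def reconstruct_softcor(
    expr: ExpressionMatrix, config: ReconstructionConfig | None = None
) -> WeightedNetwork:
    """Soft-thresholded co-expression adjacency |cor|^beta (in [0, 1])."""
    config = config or ReconstructionConfig(method="softcor")
    _check_input(expr)
    r = np.corrcoef(expr.values)
    np.clip(r, -1.0, 1.0, out=r)
    scores = np.abs(r) ** config.beta
    np.fill_diagonal(scores, 0.0)
    return WeightedNetwork(expr.gene_ids, (scores + scores.T) / 2.0)


METHODS = {
    "space": reconstruct_space,
    "shrinkage_pcor": reconstruct_shrinkage_pcor,
    "softcor": reconstruct_softcor,
}


def reconstruct(
    expr: ExpressionMatrix, method: str, config: ReconstructionConfig | None = None
) -> WeightedNetwork:
    """Dispatch to one of the baseline reconstructors by name."""
    if method not in METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return METHODS[method](expr, config)
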