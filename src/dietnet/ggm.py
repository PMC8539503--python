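"""Gaussian graphical model of log-transformed food-group intakes.

The food network is the partial-correlation graph of the 16 log
intakes: edges are entries of the inverse covariance (precision) matrix
Ω, rescaled to partial correlations ρ_ij = −ω_ij / sqrt(ω_ii ω_jj).
Ω is estimated by the graphical lasso over a descending λ grid and the
regularization level is selected with the extended Bayesian information
criterion (EBIC),

    EBIC(λ) = −2·loglik(Ω̂_λ) + E·log n + 4·γ·E·log p,

where E is the number of nonzero off-diagonal pairs and γ (default 0.5)
penalizes dense graphs beyond ordinary BIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.covariance import graphical_lasso

from dietnet.cohort import FOOD_GROUPS

__all__ = ["GGMResult", "log_transform_intakes", "fit_ggm", "partial_correlations",
           "export_adjacency", "export_edge_list"]

# partial correlations below this magnitude are numerical zeros
EDGE_TOL = 1e-6


@dataclass(frozen=True)
class GGMResult:
    node_names: tuple[str, ...]
    precision: np.ndarray
    partial_corr: np.ndarray
    lambda_path: np.ndarray
    selected_lambda: float
    ebic_trace: np.ndarray
    gamma: float
    n: int
    p: int

    def edge_set(self, tol: float = EDGE_TOL) -> set[frozenset[str]]:
        rho = self.partial_corr
        out = set()
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if abs(rho[i, j]) > tol:
                    out.add(frozenset((self.node_names[i], self.node_names[j])))
        return out


def log_transform_intakes(table: pd.DataFrame,
                          foods: tuple[str, ...] = FOOD_GROUPS) -> pd.DataFrame:
    """log(x + 1) each intake column, then standardize to mean 0, sd 1.

    Complete-case: rows with any missing intake are dropped. A +1 g
    pseudo-count keeps zero intakes finite; columns with zero variance
    after transformation are rejected by name.
    """
    missing = [f for f in foods if f not in table.columns]
    if missing:
        raise ValueError(f"missing intake columns: {missing}")
    X = table.loc[:, list(foods)].dropna(axis=0, how="any")
    if (X < 0).any().any():
        bad = X.columns[(X < 0).any()].tolist()
        raise ValueError(f"negative intakes in columns: {bad}")
    logged = np.log1p(X.astype(float))
    sd = logged.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance food group(s) after log transform: {flat}")
    return (logged - logged.mean()) / sd


def partial_correlations(omega: np.ndarray) -> np.ndarray:
    """ρ_ij = −ω_ij / sqrt(ω_ii ω_jj), with unit diagonal."""
    omega = np.asarray(omega, dtype=float)
    if not np.allclose(omega, omega.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    if np.linalg.eigvalsh(omega).min() <= 0:
        raise ValueError("precision matrix is not positive definite")
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def default_lambda_path(S: np.ndarray, n_lambdas: int = 50,
                        ratio: float = 0.01) -> np.ndarray:
    """Log-spaced grid from λ_max (empty graph) down to ratio·λ_max."""
    off = np.abs(S - np.diag(np.diag(S)))
    lam_max = float(off.max())
    if lam_max <= 0:
        raise ValueError("sample covariance has no off-diagonal signal")
    return np.geomspace(lam_max, ratio * lam_max, n_lambdas)


def _gaussian_ebic(S: np.ndarray, omega: np.ndarray, n: int, gamma: float) -> float:
    sign, logdet = np.linalg.slogdet(omega)
    if sign <= 0:
        return np.inf
    p = S.shape[0]
    neg2_loglik = n * (np.trace(S @ omega) - logdet)
    off = omega.copy()
    np.fill_diagonal(off, 0.0)
    E = int(np.count_nonzero(np.abs(np.triu(off)) > EDGE_TOL))
    return neg2_loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)


def fit_ggm(X, gamma: float = 0.5, lambda_path: np.ndarray | None = None,
            max_iter: int = 500) -> GGMResult:
    """Graphical lasso over a λ path with EBIC model selection.

    Parameters
    ----------
    X : array or DataFrame, shape (n, p)
        Standardized log intakes (see :func:`log_transform_intakes`).
    gamma : float
        EBIC density penalty; 0 recovers ordinary BIC.
    lambda_path : descending positive grid, optional
        Defaults to 50 log-spaced values spanning two decades below the
        smallest λ that empties the graph.
    """
    names = tuple(X.columns) if isinstance(X, pd.DataFrame) else tuple(
        f"x{i}" for i in range(np.asarray(X).shape[1]))
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 2 * p:
        warnings.warn(f"n={n} < 2p={2 * p}; estimates may be unstable", stacklevel=2)
    S = np.cov(X, rowvar=False, ddof=0)

    if lambda_path is None:
        lambda_path = default_lambda_path(S)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if (lambda_path <= 0).any() or (np.diff(lambda_path) >= 0).any():
        raise ValueError("lambda_path must be strictly positive and descending")

    ebic = np.empty(len(lambda_path))
    best = None
    for k, lam in enumerate(lambda_path):
        try:
            with warnings.catch_warnings():
                # tiny negative dual gaps at the dense end of the path are
                # numerical noise, not estimation failures
                warnings.simplefilter("ignore")
                _, omega = graphical_lasso(S, alpha=float(lam), max_iter=max_iter)
        except FloatingPointError as exc:
            raise RuntimeError(f"graphical lasso failed to converge at lambda={lam:.6g}") from exc
        if not np.all(np.isfinite(omega)):
            raise RuntimeError(f"graphical lasso diverged at lambda={lam:.6g}")
        ebic[k] = _gaussian_ebic(S, omega, n, gamma)
        if best is None or ebic[k] < best[0]:
            best = (ebic[k], float(lam), omega)

    _, sel_lambda, omega = best
    rho = partial_correlations(omega)
    rho[np.abs(rho) <= EDGE_TOL] = 0.0
    np.fill_diagonal(rho, 1.0)
    return GGMResult(
        node_names=names,
        precision=omega,
        partial_corr=rho,
        lambda_path=lambda_path,
        selected_lambda=sel_lambda,
        ebic_trace=ebic,
        gamma=gamma,
        n=n,
        p=p,
    )


def export_adjacency(result: GGMResult, path) -> None:
    pd.DataFrame(result.partial_corr, index=result.node_names,
                 columns=result.node_names).to_csv(path)


def export_edge_list(result: GGMResult, path) -> None:
    rows = []
    for i in range(result.p):
        for j in range(i + 1, result.p):
            w = result.partial_corr[i, j]
            if abs(w) > EDGE_TOL:
                rows.append((result.node_names[i], result.node_names[j], w))
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(path, index=False)
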