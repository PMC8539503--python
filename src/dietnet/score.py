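"""GGM-weighted dietary score.

Food-group weights are the eigenvector centrality of the estimated food
network: the leading eigenvector of the absolute partial-correlation
matrix with its diagonal zeroed. By Perron–Frobenius the leading
eigenvector of a nonnegative matrix can be taken entrywise nonnegative;
it is normalized here to unit Euclidean length (any fixed normalization
only rescales scores and leaves the tertile split unchanged).

A participant's score is the weighted sum of raw intakes in g/day,
D_i = Σ_g w_g x_ig, subsequently cut at the empirical tertiles into
light / normal / heavy eating behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dietnet.cohort import FOOD_GROUPS

__all__ = ["DietScoreResult", "eigenvector_weights", "dietary_score",
           "tertile_categorize", "score_cohort"]

TERTILE_LABELS = ("light", "normal", "heavy")


@dataclass(frozen=True)
class DietScoreResult:
    food_names: tuple[str, ...]
    weights: np.ndarray
    scores: pd.Series
    tertile: pd.Series
    tertile_cutpoints: tuple[float, float]


def eigenvector_weights(partial_corr: np.ndarray) -> np.ndarray:
    """Leading eigenvector of |ρ| with zeroed diagonal, unit 2-norm.

    Negative partial correlations enter by magnitude: eigenvector
    centrality is defined for nonnegative matrices only. Nodes outside
    the principal connected component receive weight 0.
    """
    A = np.abs(np.asarray(partial_corr, dtype=float))
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    if not A.any():
        raise ValueError("no edges; weights undefined")
    vals, vecs = np.linalg.eigh(A)
    lead = vecs[:, -1]
    # Perron vector of a nonnegative matrix: fix the sign, clip tiny
    # negative round-off from other components
    if lead.sum() < 0:
        lead = -lead
    lead = np.clip(lead, 0.0, None)
    return lead / np.linalg.norm(lead)


def dietary_score(table: pd.DataFrame, weights: np.ndarray,
                  foods: tuple[str, ...] = FOOD_GROUPS) -> pd.Series:
    """D_i = Σ_g w_g · x_ig over raw g/day intakes (not log).

    Rows with any missing intake are excluded (count reported via the
    returned index).
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(foods):
        raise ValueError(f"expected {len(foods)} weights, got {len(weights)}")
    X = table.loc[:, list(foods)].dropna(axis=0, how="any")
    scores = pd.Series(X.to_numpy(dtype=float) @ weights, index=X.index, name="diet_score")
    return scores


def tertile_categorize(scores: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    """Split scores at the 33.33% / 66.67% empirical quantiles.

    Linear-interpolation quantiles; a value tied exactly with a cutpoint
    falls in the lower tertile (intervals are closed on the right).
    """
    s = pd.Series(scores).dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 participants to form tertiles")
    if s.nunique() < 3:
        raise ValueError("fewer than 3 distinct score values; tertiles are degenerate")
    q1, q2 = np.quantile(s.to_numpy(), [1.0 / 3.0, 2.0 / 3.0])
    labels = np.where(s <= q1, TERTILE_LABELS[0],
                      np.where(s <= q2, TERTILE_LABELS[1], TERTILE_LABELS[2]))
    cat = pd.Series(pd.Categorical(labels, categories=list(TERTILE_LABELS), ordered=True),
                    index=s.index, name="diet_tertile")
    return cat, (float(q1), float(q2))


def score_cohort(table: pd.DataFrame, partial_corr: np.ndarray,
                 foods: tuple[str, ...] = FOOD_GROUPS) -> DietScoreResult:
    """Weights, scores and tertiles in one pass."""
    w = eigenvector_weights(partial_corr)
    scores = dietary_score(table, w, foods)
    tert, cuts = tertile_categorize(scores)
    return DietScoreResult(tuple(foods), w, scores, tert, cuts)
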