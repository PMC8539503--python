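"""Planted ground-truth constructions for validating network recovery.

These fix the simulation conditions used to check that the estimators
recover known structure: a sparse 16-node food GGM with five planted
partial-correlation edges, and a 12-node mixed MRF (six continuous,
six categorical nodes) with eight planted pairwise interactions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dietnet._mrf import MRFNode, MixedMRF
from dietnet.mgm import MGMSpec, NodeSpec

__all__ = ["planted_food_precision", "planted_mixed_mrf", "mixed_mrf_spec",
           "recovery_rates", "sample_gaussian"]

# disjoint planted pairs with partial correlations >= 0.3
FOOD_PLANTED_PAIRS = ((0, 1, 0.6), (2, 3, 0.5), (4, 5, 0.4), (6, 7, 0.35), (8, 9, 0.3))


def planted_food_precision(p: int = 16) -> np.ndarray:
    """Precision matrix with five disjoint planted edges, |rho| >= 0.3."""
    prec = np.eye(p)
    for i, j, rho in FOOD_PLANTED_PAIRS:
        prec[i, j] = prec[j, i] = -rho
    return prec


def sample_gaussian(precision: np.ndarray, n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(precision)
    return rng.multivariate_normal(np.zeros(len(precision)), cov, size=n,
                                   method="cholesky")


def planted_mixed_mrf() -> MixedMRF:
    """12 mixed nodes, 8 planted edges spanning all pair types."""
    nodes = [MRFNode(f"c{i}", "continuous") for i in range(6)] + [
        MRFNode(f"k{i}", "categorical", ("a", "b") if i % 2 else ("a", "b", "c"))
        for i in range(6)
    ]
    couplings = {
        (0, 1): 0.35,                                   # continuous-continuous
        (2, 3): 0.35,
        (4, 6): np.array([0.8, -0.8, 0.0]),             # continuous-categorical
        (5, 7): np.array([0.9, -0.9]),
        (6, 8): np.eye(3) * 1.2,                        # categorical-categorical
        (7, 9): np.array([[1.0, -1.0], [-1.0, 1.0]]),
        (8, 10): np.eye(3) * 1.2,
        (9, 11): np.array([[1.0, -1.0], [-1.0, 1.0]]),
    }
    return MixedMRF(nodes=nodes, couplings=couplings)


def mixed_mrf_spec(mrf: MixedMRF) -> MGMSpec:
    return MGMSpec(tuple(NodeSpec(n.name, n.kind, n.levels) for n in mrf.nodes))


def recovery_rates(estimated: set[frozenset], truth: set[frozenset],
                   n_nodes: int) -> tuple[float, float]:
    """(true-positive rate, false-positive rate) over all node pairs."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    tp = len(estimated & truth)
    fp = len(estimated - truth)
    return tp / len(truth), fp / (n_pairs - len(truth))
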