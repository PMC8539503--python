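"""Pairwise mixed Markov random field with Gibbs sampling.

The joint density over continuous nodes ``x`` and categorical nodes ``y``
is the pairwise exponential family

    p(x, y) ∝ exp( -1/2 Σ_s x_s²  +  Σ_s μ_s x_s
                   + Σ_{s<t} θ_st x_s x_t
                   + Σ_{s,r} γ_sr[y_r] x_s
                   + Σ_r α_r[y_r]  +  Σ_{r<q} φ_rq[y_r, y_q] ),

so every full conditional is closed-form: a unit-variance Gaussian for a
continuous node and a softmax over levels for a categorical node.  The
density is normalizable iff the continuous-block precision ``I - Θ`` is
positive definite, which :meth:`MixedMRF.validate` enforces.

This is both the ground-truth generator for mixed-network recovery
experiments (an edge exists exactly where a pairwise parameter is
nonzero) and, restricted to categorical nodes, the sampler behind the
synthetic demographic block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MRFNode", "MixedMRF"]


@dataclass(frozen=True)
class MRFNode:
    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown node kind {self.kind!r} for node {self.name!r}")
        if self.kind == "categorical":
            if self.levels is None or len(self.levels) < 2:
                raise ValueError(f"categorical node {self.name!r} needs >= 2 levels")
        elif self.levels is not None:
            raise ValueError(f"continuous node {self.name!r} must not declare levels")


@dataclass
class MixedMRF:
    """A pairwise MRF over mixed nodes, sampled by parallel Gibbs chains.

    Parameters
    ----------
    nodes
        Node declarations; order fixes the index used in ``couplings``.
    couplings
        Map ``(i, j) -> parameter`` with ``i < j`` (node indices).
        Shape depends on the pair: scalar for continuous–continuous,
        vector of length ``L_j`` (or ``L_i``) for mixed pairs, matrix
        ``L_i x L_j`` for categorical–categorical.
    intercepts
        Optional map ``i -> parameter``: scalar mean shift for a
        continuous node, length-``L_i`` base potential for a categorical
        node. Missing entries default to zero.
    """

    nodes: list[MRFNode]
    couplings: dict[tuple[int, int], np.ndarray | float] = field(default_factory=dict)
    intercepts: dict[int, np.ndarray | float] = field(default_factory=dict)

    def __post_init__(self):
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")
        self.couplings = {self._key(i, j): np.asarray(v, dtype=float) if np.ndim(v) else float(v)
                          for (i, j), v in self.couplings.items()}
        self.validate()

    @staticmethod
    def _key(i: int, j: int) -> tuple[int, int]:
        if i == j:
            raise ValueError("self-couplings are not allowed")
        return (i, j) if i < j else (j, i)

    # -- structure -----------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def continuous_indices(self) -> list[int]:
        return [i for i, n in enumerate(self.nodes) if n.kind == "continuous"]

    def edges(self, tol: float = 0.0) -> set[frozenset[str]]:
        """Node-name pairs whose pairwise parameter is not (all) zero."""
        out = set()
        for (i, j), v in self.couplings.items():
            if np.max(np.abs(v)) > tol:
                out.add(frozenset((self.nodes[i].name, self.nodes[j].name)))
        return out

    def validate(self) -> None:
        cont = self.continuous_indices()
        pos = {s: k for k, s in enumerate(cont)}
        prec = np.eye(len(cont))
        for (i, j), v in self.couplings.items():
            ni, nj = self.nodes[i], self.nodes[j]
            if ni.kind == "continuous" and nj.kind == "continuous":
                if np.ndim(v) != 0:
                    raise ValueError(f"coupling {ni.name}-{nj.name} must be scalar")
                prec[pos[i], pos[j]] = prec[pos[j], pos[i]] = -float(v)
            elif ni.kind == "categorical" and nj.kind == "categorical":
                if np.shape(v) != (len(ni.levels), len(nj.levels)):
                    raise ValueError(f"coupling {ni.name}-{nj.name} has wrong shape {np.shape(v)}")
            else:
                cat = ni if ni.kind == "categorical" else nj
                if np.shape(v) != (len(cat.levels),):
                    raise ValueError(f"coupling {ni.name}-{nj.name} has wrong shape {np.shape(v)}")
        if cont and np.linalg.eigvalsh(prec).min() <= 0:
            raise ValueError("continuous-block precision I - Theta is not positive definite")

    # -- sampling --------------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator,
               burn_in: int = 500, thin: int = 10) -> dict[str, np.ndarray]:
        """Draw ``n`` independent joint samples by running ``n`` parallel
        Gibbs chains for ``burn_in + thin`` full sweeps.

        Returns a map from node name to an array of length ``n``
        (floats for continuous nodes, level strings for categorical).
        """
        state: dict[int, np.ndarray] = {}
        for i, node in enumerate(self.nodes):
            if node.kind == "continuous":
                state[i] = rng.standard_normal(n)
            else:
                state[i] = rng.integers(0, len(node.levels), size=n)

        neighbors: dict[int, list[tuple[int, np.ndarray | float, bool]]] = {i: [] for i in range(len(self.nodes))}
        for (i, j), v in self.couplings.items():
            neighbors[i].append((j, v, False))   # v oriented i -> j
            neighbors[j].append((i, v, True))    # transposed view

        for sweep in range(burn_in + thin):
            for i, node in enumerate(self.nodes):
                if node.kind == "continuous":
                    mean = np.full(n, float(self.intercepts.get(i, 0.0)))
                    for j, v, flipped in neighbors[i]:
                        other = self.nodes[j]
                        if other.kind == "continuous":
                            mean += float(v) * state[j]
                        else:
                            mean += np.asarray(v)[state[j]]
                    state[i] = mean + rng.standard_normal(n)
                else:
                    L = len(node.levels)
                    logits = np.tile(np.asarray(self.intercepts.get(i, np.zeros(L)), dtype=float), (n, 1))
                    for j, v, flipped in neighbors[i]:
                        other = self.nodes[j]
                        if other.kind == "continuous":
                            logits += np.outer(state[j], np.asarray(v))
                        else:
                            mat = np.asarray(v)
                            if flipped:
                                mat = mat.T
                            # mat is now L_i x L_j: pick the column of y_j
                            logits += mat[:, state[j]].T
                    gumbel = rng.gumbel(size=(n, L))
                    state[i] = np.argmax(logits + gumbel, axis=1)

        out: dict[str, np.ndarray] = {}
        for i, node in enumerate(self.nodes):
            if node.kind == "continuous":
                out[node.name] = state[i]
            else:
                out[node.name] = np.asarray(node.levels, dtype=object)[state[i]]
        return out
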