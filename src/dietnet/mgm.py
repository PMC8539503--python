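"""Mixed graphical model by nodewise ℓ1-regularized regressions.

Each variable (node) is regressed on all others: continuous nodes by
lasso least squares, categorical nodes by ℓ1-penalized multinomial
logistic regression with one indicator column per level of every
categorical predictor (over-complete coding, so levels are treated
symmetrically). Each nodewise fit selects its own λ on a 30-point
log-spaced path by the extended BIC,

    continuous:   EBIC(λ) = n·log(RSS/n) + df·log n + 2γ·df·log P
    categorical:  EBIC(λ) = −2·loglik    + df·log n + 2γ·df·log P

with df the number of nonzero coefficients and P the number of
candidate predictor columns.

An edge (i, j) aggregates every coefficient linking the two nodes from
both nodewise fits. Under the AND rule the edge survives only when
each direction contributes at least one nonzero coefficient; its
weight is the mean absolute value of all collected coefficients. Edge
signs are defined for continuous–continuous pairs when both directions
agree, otherwise recorded as 0 (undeterminable), which is always the
case for pairs involving a categorical node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, lasso_path

__all__ = ["NodeSpec", "MGMSpec", "NodewiseFit", "MGMNetwork",
           "encode_design", "nodewise_fit", "aggregate_edges",
           "predictability", "fit_mgm"]

COEF_TOL = 1e-8


@dataclass(frozen=True)
class NodeSpec:
    name: str
    kind: str  # "continuous" | "categorical"
    levels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r} for node {self.name!r}")
        if self.kind == "categorical" and (self.levels is None or len(self.levels) < 2):
            raise ValueError(f"categorical node {self.name!r} needs >= 2 levels")


@dataclass(frozen=True)
class MGMSpec:
    nodes: tuple[NodeSpec, ...]

    def __post_init__(self):
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("node names must be unique")

    @property
    def names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def __getitem__(self, name: str) -> NodeSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @classmethod
    def from_table(cls, table: pd.DataFrame, continuous: list[str],
                   categorical: dict[str, tuple[str, ...]] | list[str]) -> "MGMSpec":
        nodes = [NodeSpec(c, "continuous") for c in continuous]
        if isinstance(categorical, dict):
            items = categorical.items()
        else:
            items = [(c, tuple(sorted(table[c].dropna().astype(str).unique())))
                     for c in categorical]
        nodes += [NodeSpec(c, "categorical", tuple(lv)) for c, lv in items]
        return cls(tuple(nodes))


@dataclass
class EncodedDesign:
    X: pd.DataFrame                       # n x P numeric design
    col_map: dict[str, list[str]]         # node -> its columns in X
    y_codes: dict[str, np.ndarray]        # categorical node -> level codes
    levels: dict[str, tuple[str, ...]]    # categorical node -> retained levels
    raw_continuous: dict[str, np.ndarray]
    index: pd.Index


def encode_design(table: pd.DataFrame, spec: MGMSpec) -> EncodedDesign:
    """Complete-case design matrix with standardized continuous columns
    and one 0/1 indicator per categorical level.

    Levels declared but never observed are dropped with a warning.
    """
    cols = spec.names
    data = table.loc[:, cols].dropna(axis=0, how="any")
    if len(data) == 0:
        raise ValueError("no complete-case rows for the requested nodes")
    blocks: dict[str, pd.DataFrame] = {}
    col_map: dict[str, list[str]] = {}
    y_codes: dict[str, np.ndarray] = {}
    kept_levels: dict[str, tuple[str, ...]] = {}
    raw_cont: dict[str, np.ndarray] = {}
    for node in spec.nodes:
        if node.kind == "continuous":
            x = data[node.name].to_numpy(dtype=float)
            sd = x.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero-variance continuous node {node.name!r}")
            blocks[node.name] = pd.DataFrame({node.name: (x - x.mean()) / sd},
                                             index=data.index)
            col_map[node.name] = [node.name]
            raw_cont[node.name] = x
        else:
            observed = data[node.name].astype(str)
            levels = tuple(lv for lv in node.levels if (observed == lv).any())
            dropped = set(node.levels) - set(levels)
            if dropped:
                warnings.warn(
                    f"node {node.name!r}: dropping unobserved level(s) {sorted(dropped)}",
                    stacklevel=2)
            if len(levels) < 2:
                raise ValueError(f"node {node.name!r} has < 2 observed levels")
            codes = pd.Categorical(observed, categories=levels).codes
            ind = np.zeros((len(data), len(levels)))
            ind[np.arange(len(data)), codes] = 1.0
            names = [f"{node.name}={lv}" for lv in levels]
            blocks[node.name] = pd.DataFrame(ind, columns=names, index=data.index)
            col_map[node.name] = names
            y_codes[node.name] = codes
            kept_levels[node.name] = levels
    X = pd.concat([blocks[n.name] for n in spec.nodes], axis=1)
    return EncodedDesign(X=X, col_map=col_map, y_codes=y_codes,
                         levels=kept_levels, raw_continuous=raw_cont,
                         index=data.index)


@dataclass
class NodewiseFit:
    node: str
    kind: str
    coef: pd.DataFrame          # (response dims) x (predictor columns)
    intercept: np.ndarray
    selected_lambda: float
    lambda_path: np.ndarray
    ebic_trace: np.ndarray
    predict_cols: list[str]
    predictability_: float = field(default=np.nan)


def _lambda_path_from_max(lam_max: float, n_lambdas: int, ratio: float = 0.01) -> np.ndarray:
    lam_max = max(lam_max, 1e-8)
    return np.geomspace(lam_max, ratio * lam_max, n_lambdas)


def _fit_continuous(node: str, X: np.ndarray, y: np.ndarray, gamma: float,
                    n_lambdas: int, pred_cols: list[str]) -> NodewiseFit:
    n, P = X.shape
    Xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - Xm, y - ym
    lam_max = np.max(np.abs(Xc.T @ yc)) / n
    path = _lambda_path_from_max(lam_max, n_lambdas)
    _, coefs, _ = lasso_path(Xc, yc, alphas=path)
    # lasso_path returns alphas descending to match input order
    rss = np.sum((yc[:, None] - Xc @ coefs) ** 2, axis=0)
    df = np.count_nonzero(np.abs(coefs) > COEF_TOL, axis=0)
    ebic = n * np.log(np.maximum(rss, 1e-300) / n) + df * np.log(n) \
        + 2.0 * gamma * df * np.log(P)
    k = int(np.argmin(ebic))
    beta = coefs[:, k]
    beta[np.abs(beta) <= COEF_TOL] = 0.0
    intercept = ym - Xm @ beta
    tss = float(np.sum(yc ** 2))
    r2 = 1.0 - float(rss[k]) / tss if tss > 0 else 0.0
    fit = NodewiseFit(node=node, kind="continuous",
                      coef=pd.DataFrame(beta[None, :], index=["coef"], columns=pred_cols),
                      intercept=np.array([intercept]),
                      selected_lambda=float(path[k]),
                      lambda_path=path, ebic_trace=ebic, predict_cols=pred_cols)
    fit.predictability_ = max(r2, 0.0)
    return fit


def _multinomial_lambda_max(X: np.ndarray, Y: np.ndarray) -> float:
    # KKT entry point: max |x_j' (1{y=k} - pbar_k)| / n over features and classes
    n = X.shape[0]
    pbar = Y.mean(axis=0)
    return float(np.max(np.abs(X.T @ (Y - pbar))) / n)


def _fit_categorical(node: str, X: np.ndarray, codes: np.ndarray,
                     levels: tuple[str, ...], gamma: float, n_lambdas: int,
                     pred_cols: list[str]) -> NodewiseFit:
    n, P = X.shape
    K = len(levels)
    Y = np.zeros((n, K))
    Y[np.arange(n), codes] = 1.0
    lam_max = _multinomial_lambda_max(X, Y)
    path = _lambda_path_from_max(lam_max, n_lambdas)

    model = LogisticRegression(l1_ratio=1.0, solver="saga", warm_start=True,
                               fit_intercept=True, max_iter=3000, tol=1e-4,
                               random_state=0)
    ebic = np.empty(len(path))
    best = None
    # at lambda_max the exact solution is the intercept-only model; fitting
    # there numerically sits on the KKT boundary, so use the analytic null
    pbar = np.clip(Y.mean(axis=0), 1e-12, None)
    ll0 = float(np.sum(Y.sum(axis=0) * np.log(pbar)))
    ebic[0] = -2.0 * ll0
    best = (ebic[0], float(path[0]), np.zeros((K, P)), np.log(pbar))
    for k, lam in enumerate(path):
        if k == 0:
            continue
        model.C = 1.0 / (n * float(lam))
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=ConvergenceWarning)
            try:
                model.fit(X, codes)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"nodewise fit for {node!r} did not converge at lambda={lam:.5g}"
                ) from exc
        prob = np.clip(model.predict_proba(X), 1e-12, None)
        ll = float(np.sum(np.log(prob[np.arange(n), codes])))
        df = int(np.count_nonzero(np.abs(model.coef_) > COEF_TOL))
        ebic[k] = -2.0 * ll + df * np.log(n) + 2.0 * gamma * df * np.log(P)
        if best is None or ebic[k] < best[0]:
            best = (ebic[k], float(lam), model.coef_.copy(), model.intercept_.copy())

    _, sel, coef, intercept = best
    coef = coef.copy()
    coef[np.abs(coef) <= COEF_TOL] = 0.0
    if coef.shape[0] == 1 and K == 2:
        # sklearn's binary parameterization: expand to symmetric 2-row form
        coef = np.vstack([-coef[0] / 2.0, coef[0] / 2.0])
        intercept = np.array([-intercept[0] / 2.0, intercept[0] / 2.0])
    fit = NodewiseFit(node=node, kind="categorical",
                      coef=pd.DataFrame(coef, index=list(levels), columns=pred_cols),
                      intercept=np.asarray(intercept, dtype=float),
                      selected_lambda=sel, lambda_path=path, ebic_trace=ebic,
                      predict_cols=pred_cols)
    logits = X @ coef.T + fit.intercept
    fit.predictability_ = float(np.mean(np.argmax(logits, axis=1) == codes))
    return fit


def nodewise_fit(node: str, design: EncodedDesign, spec: MGMSpec,
                 gamma: float = 0.5, n_lambdas: int = 30) -> NodewiseFit:
    """EBIC-selected ℓ1 regression of one node on all other nodes."""
    ns = spec[node]
    own = set(design.col_map[node])
    pred_cols = [c for c in design.X.columns if c not in own]
    X = design.X.loc[:, pred_cols].to_numpy(dtype=float)
    if ns.kind == "continuous":
        y = design.X[node].to_numpy(dtype=float)  # standardized response
        return _fit_continuous(node, X, y, gamma, n_lambdas, pred_cols)
    return _fit_categorical(node, X, design.y_codes[node], design.levels[node],
                            gamma, n_lambdas, pred_cols)


@dataclass
class MGMNetwork:
    spec: MGMSpec
    weight: np.ndarray
    sign: np.ndarray
    per_node_lambda: pd.Series
    predictability: pd.Series
    gamma: float
    rule: str
    fits: dict[str, NodewiseFit] | None = None

    @property
    def names(self) -> list[str]:
        return self.spec.names

    def edge_set(self, tol: float = 0.0) -> set[frozenset[str]]:
        names = self.names
        out = set()
        p = len(names)
        for i in range(p):
            for j in range(i + 1, p):
                if self.weight[i, j] > tol:
                    out.add(frozenset((names[i], names[j])))
        return out

    def edge_frame(self) -> pd.DataFrame:
        names = self.names
        rows = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if self.weight[i, j] > 0:
                    rows.append((names[i], names[j], self.weight[i, j],
                                 int(self.sign[i, j])))
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "sign"])


def _cross_block(fit: NodewiseFit, other: str, col_map: dict[str, list[str]]) -> np.ndarray:
    cols = [c for c in col_map[other] if c in fit.coef.columns]
    return fit.coef.loc[:, cols].to_numpy(dtype=float).ravel()


def aggregate_edges(fits: dict[str, NodewiseFit], spec: MGMSpec,
                    design: EncodedDesign, gamma: float,
                    rule: str = "AND") -> MGMNetwork:
    """Combine nodewise coefficient blocks into one symmetric network."""
    if rule not in ("AND", "OR"):
        raise ValueError("rule must be 'AND' or 'OR'")
    names = spec.names
    p = len(names)
    weight = np.zeros((p, p))
    sign = np.zeros((p, p), dtype=int)
    for i in range(p):
        for j in range(i + 1, p):
            bi = _cross_block(fits[names[i]], names[j], design.col_map)
            bj = _cross_block(fits[names[j]], names[i], design.col_map)
            nz_i = np.any(np.abs(bi) > COEF_TOL)
            nz_j = np.any(np.abs(bj) > COEF_TOL)
            keep = (nz_i and nz_j) if rule == "AND" else (nz_i or nz_j)
            if not keep:
                continue
            allc = np.concatenate([bi, bj])
            w = float(np.mean(np.abs(allc)))
            weight[i, j] = weight[j, i] = w
            ni, nj = spec.nodes[i], spec.nodes[j]
            if ni.kind == "continuous" and nj.kind == "continuous" and nz_i and nz_j:
                si, sj = np.sign(bi[np.abs(bi) > COEF_TOL]), np.sign(bj[np.abs(bj) > COEF_TOL])
                s = int(si[0]) if (len(si) and len(sj) and si[0] == sj[0]) else 0
                sign[i, j] = sign[j, i] = s
    lam = pd.Series({n: fits[n].selected_lambda for n in names})
    pred = pd.Series({n: fits[n].predictability_ for n in names})
    return MGMNetwork(spec=spec, weight=weight, sign=sign, per_node_lambda=lam,
                      predictability=pred, gamma=gamma, rule=rule, fits=fits)


def predictability(fits: dict[str, NodewiseFit], design: EncodedDesign,
                   spec: MGMSpec) -> pd.Series:
    """Per-node fit quality recomputed from stored coefficients.

    Continuous nodes: explained variance 1 − RSS/TSS of the nodewise
    fit. Categorical nodes: fraction of rows whose argmax predicted
    category matches the observed one.
    """
    out = {}
    for node, fit in fits.items():
        X = design.X.loc[:, fit.predict_cols].to_numpy(dtype=float)
        if fit.kind == "continuous":
            y = design.X[node].to_numpy(dtype=float)
            yhat = X @ fit.coef.to_numpy()[0] + fit.intercept[0]
            tss = float(np.sum((y - y.mean()) ** 2))
            out[node] = max(0.0, 1.0 - float(np.sum((y - yhat) ** 2)) / tss) if tss else 0.0
        else:
            codes = design.y_codes[node]
            logits = X @ fit.coef.to_numpy().T + fit.intercept
            out[node] = float(np.mean(np.argmax(logits, axis=1) == codes))
    return pd.Series(out)


def fit_mgm(table: pd.DataFrame, spec: MGMSpec, gamma: float = 0.5,
            n_lambdas: int = 30, rule: str = "AND") -> MGMNetwork:
    """Full mixed-graphical-model estimate: encode, fit nodewise, aggregate."""
    design = encode_design(table, spec)
    fits = {name: nodewise_fit(name, design, spec, gamma=gamma, n_lambdas=n_lambdas)
            for name in spec.names}
    return aggregate_edges(fits, spec, design, gamma=gamma, rule=rule)
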