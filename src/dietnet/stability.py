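"""Bootstrap accuracy and case-dropping stability of the MGM network.

Accuracy: nonparametric bootstrap — each replicate resamples
``ceil(resample_frac * n)`` rows *with* replacement (the study design
resamples 80% of the sample), refits the network, and records every
edge weight; per-edge quantile confidence intervals summarize the
replicate store. Pairwise bootstrap difference tests flag edge pairs
(and node-strength pairs) whose difference interval excludes zero; the
intervals are unadjusted for multiplicity.

Stability: case-dropping subset bootstrap — for each drop fraction f
in the grid, B subsamples of (1−f)·n rows *without* replacement are
refit and the subsample centrality is correlated with the full-sample
centrality. The correlation-stability (CS) coefficient is the largest
f for which that correlation is ≥ 0.7 in at least 95% of subsamples
(0 if no fraction qualifies).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dietnet.centrality import betweenness, closeness, strength
from dietnet.mgm import MGMNetwork, MGMSpec, fit_mgm

__all__ = ["StabilityReport", "bootstrap_edges", "difference_tests",
           "case_dropping_cs", "DEFAULT_DROP_GRID"]

log = logging.getLogger(__name__)

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))

_STATISTICS = {"strength": strength, "closeness": closeness, "betweenness": betweenness}


@dataclass
class StabilityReport:
    edge_ci: pd.DataFrame                  # index edge, columns mean/lower/upper
    replicates: pd.DataFrame               # B x edges store
    edge_diff: pd.DataFrame | None = None
    strength_diff: pd.DataFrame | None = None
    cs: dict[str, float] = field(default_factory=dict)
    B: int = 0
    resample_frac: float = 1.0
    seed: int | None = None
    n_failed: int = 0


def _edge_columns(spec: MGMSpec) -> list[tuple[str, str]]:
    names = spec.names
    return [(names[i], names[j]) for i in range(len(names))
            for j in range(i + 1, len(names))]


def _edge_vector(net: MGMNetwork, pairs: list[tuple[str, str]]) -> np.ndarray:
    names = net.names
    pos = {n: k for k, n in enumerate(names)}
    return np.array([net.weight[pos[a], pos[b]] for a, b in pairs])


def bootstrap_edges(table: pd.DataFrame, spec: MGMSpec, B: int = 200,
                    resample_frac: float = 0.8, seed: int = 0,
                    gamma: float = 0.5, n_lambdas: int = 30) -> StabilityReport:
    """Edge-weight bootstrap; deterministic in ``seed``.

    Replicates whose network fit fails are dropped and logged; more
    than 10% failures abort the run.
    """
    if not (0 < resample_frac <= 1):
        raise ValueError("resample_frac must lie in (0, 1]")
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        warnings.warn(f"B={B} replicates; >= 100 recommended for stable intervals",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(table)
    m = math.ceil(resample_frac * n)
    pairs = _edge_columns(spec)
    rows, failed = [], 0
    for b in range(B):
        idx = rng.integers(0, n, size=m)
        sample = table.iloc[idx].reset_index(drop=True)
        try:
            net = fit_mgm(sample, spec, gamma=gamma, n_lambdas=n_lambdas)
        except (RuntimeError, ValueError) as exc:
            failed += 1
            log.warning("bootstrap replicate %d dropped: %s", b, exc)
            if failed > 0.1 * B:
                raise RuntimeError(f"more than 10% of bootstrap replicates failed "
                                   f"({failed}/{b + 1})") from exc
            continue
        rows.append(_edge_vector(net, pairs))
    store = pd.DataFrame(np.asarray(rows), columns=[f"{a}|{b}" for a, b in pairs])
    mean = store.mean()
    # quantile intervals widened to contain the bootstrap mean: for edges
    # selected in only a handful of replicates the replicate distribution is
    # a point mass at zero plus outliers, leaving the mean above q97.5
    ci = pd.DataFrame({
        "mean": mean,
        "lower": np.minimum(store.quantile(0.025), mean),
        "upper": np.maximum(store.quantile(0.975), mean),
    })
    return StabilityReport(edge_ci=ci, replicates=store, B=B,
                           resample_frac=resample_frac, seed=seed, n_failed=failed)


def difference_tests(report: StabilityReport, alpha: float = 0.05
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bootstrapped pairwise difference flags for edges and strengths.

    A pair is flagged when the (1−alpha) quantile interval of the
    bootstrap distribution of its difference excludes zero. Intervals
    are not adjusted for multiplicity.
    """
    store = report.replicates
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)

    def flag_matrix(df: pd.DataFrame) -> pd.DataFrame:
        cols = df.columns
        vals = df.to_numpy()
        k = len(cols)
        out = np.zeros((k, k), dtype=bool)
        for i in range(k):
            diffs = vals[:, i][:, None] - vals[:, i + 1:]
            if diffs.size == 0:
                continue
            lower = np.percentile(diffs, lo, axis=0)
            upper = np.percentile(diffs, hi, axis=0)
            sig = (lower > 0) | (upper < 0)
            out[i, i + 1:] = sig
            out[i + 1:, i] = sig
        return pd.DataFrame(out, index=cols, columns=cols)

    edge_diff = flag_matrix(store)

    nodes = sorted({n for c in store.columns for n in c.split("|")})
    svals = pd.DataFrame(0.0, index=store.index, columns=nodes)
    for c in store.columns:
        a, b = c.split("|")
        svals[a] += store[c]
        svals[b] += store[c]
    strength_diff = flag_matrix(svals)

    report.edge_diff = edge_diff
    report.strength_diff = strength_diff
    return edge_diff, strength_diff


def case_dropping_cs(table: pd.DataFrame, spec: MGMSpec, statistic: str = "strength",
                     drop_grid=DEFAULT_DROP_GRID, B: int = 100, seed: int = 0,
                     gamma: float = 0.5, n_lambdas: int = 30,
                     corr_threshold: float = 0.7, retention: float = 0.95
                     ) -> tuple[float, pd.DataFrame]:
    """Correlation-stability coefficient for one centrality statistic.

    Returns ``(cs, detail)`` where ``detail`` has one row per drop
    fraction with the pass rate. Subsamples on which the statistic is
    degenerate (constant, so the correlation is undefined) are recorded
    as missing and excluded from the retention tally with a warning.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {sorted(_STATISTICS)}")
    stat = _STATISTICS[statistic]
    grid = sorted(float(f) for f in drop_grid)
    if any(not (0 < f < 1) for f in grid):
        raise ValueError("drop fractions must lie in (0, 1)")

    full = fit_mgm(table, spec, gamma=gamma, n_lambdas=n_lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = stat(full.weight, full.names).to_numpy()

    rng = np.random.default_rng(seed)
    n = len(table)
    rows = []
    for f in grid:
        keep = int(round((1.0 - f) * n))
        passes, valid, missing = 0, 0, 0
        for _ in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            try:
                net = fit_mgm(table.iloc[idx].reset_index(drop=True), spec,
                              gamma=gamma, n_lambdas=n_lambdas)
            except (RuntimeError, ValueError):
                missing += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = stat(net.weight, net.names).to_numpy()
            if np.std(sub) == 0 or np.std(ref) == 0:
                missing += 1
                continue
            valid += 1
            r = float(np.corrcoef(sub, ref)[0, 1])
            if r >= corr_threshold:
                passes += 1
        if missing:
            warnings.warn(f"drop fraction {f}: {missing}/{B} subsamples had an "
                          f"undefined {statistic} correlation and were excluded",
                          stacklevel=2)
        rate = passes / valid if valid else 0.0
        rows.append((f, valid, passes, rate))
    detail = pd.DataFrame(rows, columns=["drop_frac", "n_valid", "n_pass", "pass_rate"])
    passing = detail.loc[detail["pass_rate"] >= retention, "drop_frac"]
    cs = float(passing.max()) if len(passing) else 0.0
    return cs, detail
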