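"""End-to-end orchestration: simulate/load → filter → classify → GGM →
dietary score → MGM → centrality → stability → association.

Every stage is a pure function of (input table, config, seed). A single
run seed is fanned out to named per-stage substreams (CRC32 of the
stage name mixed into a ``SeedSequence``) so each stage is
independently reproducible. All artifacts are written as CSV/JSON into
the run directory together with a manifest recording the seed, the
configuration, an input hash and the artifact list; re-running the same
configuration and seed reproduces the outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from dietnet import association, cohort, ggm, mgm, score, stability
from dietnet.centrality import centrality_table
from dietnet.cohort import DEMO_LEVELS, FOOD_GROUPS, MARKER_LEVELS

__all__ = ["RunConfig", "run_pipeline", "build_mgm_spec"]

STAGES = ("filter", "classify", "ggm", "score", "mgm", "centrality",
          "stability", "associate")


@dataclass(frozen=True)
class RunConfig:
    input_path: str | None = None          # CSV cohort; None -> simulate
    n_participants: int = 1000             # simulate block
    missing_rate: float = 0.01
    gamma: float = 0.5
    ggm_n_lambdas: int = 50
    mgm_n_lambdas: int = 30
    boot_B: int = 50
    resample_frac: float = 0.8
    drop_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    cs_B: int = 10
    cs_statistic: str = "strength"
    seed: int = 0
    out_dir: str = "dietnet_run"

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.boot_B < 1 or self.cs_B < 1:
            raise ValueError("bootstrap replicate counts must be >= 1")
        if not (0 < self.resample_frac <= 1):
            raise ValueError("resample_frac must lie in (0, 1]")
        if self.n_participants < 10:
            raise ValueError("n_participants must be >= 10")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "drop_grid" in raw:
            raw["drop_grid"] = tuple(float(x) for x in raw["drop_grid"])
        return cls(**raw)


def stage_seed(run_seed: int, stage: str) -> int:
    """Named substream: deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(run_seed) % (2**31), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def build_mgm_spec(table: pd.DataFrame) -> mgm.MGMSpec:
    """Nodes of the main network: dietary score (continuous), the ten
    demographic categoricals, and the four comorbidity markers."""
    nodes = [mgm.NodeSpec("diet_score", "continuous")]
    for name, levels in DEMO_LEVELS.items():
        nodes.append(mgm.NodeSpec(name, "categorical", levels))
    for name, levels in MARKER_LEVELS.items():
        nodes.append(mgm.NodeSpec(name, "categorical", levels))
    return mgm.MGMSpec(tuple(n for n in nodes if n.name in table.columns))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _export_graphml(weight, names, path: Path) -> None:
    G = nx.Graph()
    G.add_nodes_from(names)
    p = len(names)
    for i in range(p):
        for j in range(i + 1, p):
            if weight[i, j] > 0:
                G.add_edge(names[i], names[j], weight=float(weight[i, j]))
    nx.write_graphml(G, path)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    On a stage failure, artifacts produced so far are retained and the
    manifest records the failure point.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "status": "running",
    }
    artifacts: dict[str, Path] = {}

    def save_df(name: str, df: pd.DataFrame, **kw):
        path = out / name
        df.to_csv(path, **kw)
        artifacts[name] = path
        return path

    def done(stage: str, *names: str):
        manifest["stages"][stage] = {"outputs": list(names), "status": "ok"}

    current = "load"
    try:
        # -- input ------------------------------------------------------
        if config.input_path:
            table = cohort.read_cohort(config.input_path)
            manifest["input_sha256"] = _sha256(Path(config.input_path))
        else:
            sim = cohort.default_config(
                n_participants=config.n_participants,
                seed=stage_seed(config.seed, "simulate"),
                missing_rate=config.missing_rate,
            )
            table = cohort.generate_cohort(sim)
            save_df("cohort.csv", table, na_rep=cohort.MISSING_SENTINEL)
            manifest["input_sha256"] = _sha256(out / "cohort.csv")
            manifest["stages"]["simulate"] = {"outputs": ["cohort.csv"], "status": "ok"}

        # -- filter -----------------------------------------------------
        current = "filter"
        table, exclusions = association.apply_filters(table)
        save_df("filtered.csv", table, na_rep=cohort.MISSING_SENTINEL)
        (out / "exclusions.json").write_text(json.dumps(exclusions, indent=2))
        artifacts["exclusions.json"] = out / "exclusions.json"
        done("filter", "filtered.csv", "exclusions.json")

        # -- classify ---------------------------------------------------
        current = "classify"
        table = association.classify_markers(table)
        save_df("classified.csv", table, na_rep=cohort.MISSING_SENTINEL)
        done("classify", "classified.csv")

        # -- GGM on log intakes -----------------------------------------
        current = "ggm"
        X = ggm.log_transform_intakes(table)
        gres = ggm.fit_ggm(X, gamma=config.gamma,
                           lambda_path=ggm.default_lambda_path(
                               np.cov(np.asarray(X), rowvar=False, ddof=0),
                               n_lambdas=config.ggm_n_lambdas))
        ggm.export_adjacency(gres, out / "ggm_adjacency.csv")
        ggm.export_edge_list(gres, out / "ggm_edges.csv")
        artifacts["ggm_adjacency.csv"] = out / "ggm_adjacency.csv"
        artifacts["ggm_edges.csv"] = out / "ggm_edges.csv"
        done("ggm", "ggm_adjacency.csv", "ggm_edges.csv")

        # -- dietary score ----------------------------------------------
        current = "score"
        sres = score.score_cohort(table, gres.partial_corr)
        save_df("diet_weights.csv",
                pd.DataFrame({"food": sres.food_names, "weight": sres.weights}),
                index=False)
        scored = pd.DataFrame({"diet_score": sres.scores, "diet_tertile": sres.tertile})
        save_df("diet_scores.csv", scored)
        table = table.join(scored)
        done("score", "diet_weights.csv", "diet_scores.csv")

        # -- MGM --------------------------------------------------------
        current = "mgm"
        spec = build_mgm_spec(table)
        net = mgm.fit_mgm(table, spec, gamma=config.gamma,
                          n_lambdas=config.mgm_n_lambdas)
        save_df("mgm_adjacency.csv",
                pd.DataFrame(net.weight, index=net.names, columns=net.names))
        save_df("mgm_edges.csv", net.edge_frame(), index=False)
        save_df("predictability.csv", net.predictability.rename("predictability").to_frame())
        _export_graphml(net.weight, net.names, out / "mgm_network.graphml")
        artifacts["mgm_network.graphml"] = out / "mgm_network.graphml"
        from dietnet.viz import plot_network
        plot_network(net.weight, net.names, out / "mgm_network.png",
                     predictability=net.predictability)
        done("mgm", "mgm_adjacency.csv", "mgm_edges.csv", "predictability.csv",
             "mgm_network.graphml", "mgm_network.png")

        # -- centrality -------------------------------------------------
        current = "centrality"
        cent = centrality_table(net.weight, net.names)
        save_df("centrality.csv", cent.table)
        from dietnet.viz import plot_centrality_profile
        plot_centrality_profile(cent.table, out / "centrality_profile.png")
        done("centrality", "centrality.csv", "centrality_profile.png")

        # -- stability --------------------------------------------------
        current = "stability"
        complete = table.loc[:, spec.names].dropna()
        report = stability.bootstrap_edges(
            complete, spec, B=config.boot_B, resample_frac=config.resample_frac,
            seed=stage_seed(config.seed, "stability"), gamma=config.gamma,
            n_lambdas=config.mgm_n_lambdas)
        stability.difference_tests(report)
        save_df("stability_edge_ci.csv", report.edge_ci)
        save_df("stability_edge_diff.csv", report.edge_diff)
        save_df("stability_strength_diff.csv", report.strength_diff)
        cs, detail = stability.case_dropping_cs(
            complete, spec, statistic=config.cs_statistic,
            drop_grid=config.drop_grid, B=config.cs_B,
            seed=stage_seed(config.seed, "cs"), gamma=config.gamma,
            n_lambdas=config.mgm_n_lambdas)
        detail["cs"] = cs
        save_df("stability_cs.csv", detail, index=False)
        done("stability", "stability_edge_ci.csv", "stability_edge_diff.csv",
             "stability_strength_diff.csv", "stability_cs.csv")

        # -- association ------------------------------------------------
        current = "associate"
        predictors = {
            "age_group": DEMO_LEVELS["age_group"][0],
            "sex": "male",
            "smoking": "never",
            "bmi_group": DEMO_LEVELS["bmi_group"][0],
            "diet_tertile": "light",
        }
        tables = []
        for marker, levels in MARKER_LEVELS.items():
            ors = association.multinomial_or(table, marker, levels[0], predictors)
            ors.insert(0, "marker", marker)
            tables.append(ors)
        save_df("association_or.csv", pd.concat(tables, ignore_index=True), index=False)
        done("associate", "association_or.csv")

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        _write_manifest(out, manifest, artifacts)
        raise

    _write_manifest(out, manifest, artifacts)
    return out


def _write_manifest(out: Path, manifest: dict, artifacts: dict[str, Path]) -> None:
    manifest["artifacts"] = {name: _sha256(path) for name, path in sorted(artifacts.items())}
    try:
        from dietnet import __version__
        manifest["version"] = __version__
    except Exception:
        pass
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
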