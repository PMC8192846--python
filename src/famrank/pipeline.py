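"""Pipeline orchestration: simulate → featurize → categorize → cluster →
predict → evaluate, with a run manifest that permits bit-identical re-runs.

Every stage writes plain TSV/JSON artifacts into the output directory and
records their SHA-256 checksums in ``manifest.json``; all randomness flows
from a single master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import categorize, consensus, ensemble, evaluate, feature_table, simulate

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """One config drives the whole run; file paths may be absent when the
    simulate stage generates the inputs."""

    outdir: str = "famrank_run"
    master_seed: int = 0
    # inputs (ignored when simulate=True)
    simulate: bool = True
    feature_table_path: str | None = None
    expression_path: str | None = None
    evidence_path: str | None = None
    truth_path: str | None = None
    # simulation
    sim: dict = field(default_factory=dict)
    # analysis
    feature_set: str = "reduced10"
    cluster_k: int = 3
    cluster_reps: int = 100
    cluster_p_item: float = 0.8
    cluster_max_k: int = 6
    classifier: str = "mlp"
    n_rounds: int = 10
    n_resamples: int = 1000
    vote_threshold: int = 950
    min_rounds: int = 9
    neg_ratio: int = 3
    train_fraction: float = 2.0 / 3.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not isinstance(self.master_seed, int):
            raise ConfigError("master_seed must be an integer")
        if not self.simulate:
            for name in ("feature_table_path", "evidence_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigError(f"input path missing or absent: {name}={p!r}")
            for name in ("expression_path", "truth_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"input path absent: {name}={p!r}")
        if self.vote_threshold > self.n_resamples:
            raise ConfigError("vote_threshold exceeds n_resamples")
        if self.min_rounds > self.n_rounds:
            raise ConfigError("min_rounds exceeds n_rounds")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", **kw)


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "version": pkg_version("famrank"),
        "stages": {},
        "seeds": {s: _stage_seed(config.master_seed, s)
                  for s in ("simulate", "cluster", "predict", "evaluate")},
        "status": "running",
    }

    def record(stage: str, files: dict[str, Path], extra: dict | None = None):
        manifest["stages"][stage] = {
            "files": {k: {"path": str(p), "sha256": _sha256(p)}
                      for k, p in files.items()},
            **(extra or {}),
        }

    try:
        # --- simulate / load --------------------------------------------
        if config.simulate:
            sim_cfg = simulate.SimConfig(
                seed=manifest["seeds"]["simulate"], **config.sim)
            fam = simulate.generate_family(sim_cfg)
            features, expression, evidence, truth = fam
            paths = {
                "features": outdir / "feature_table.tsv",
                "expression": outdir / "expression.tsv",
                "evidence": outdir / "evidence.tsv",
                "truth": outdir / "truth.tsv",
            }
            _write_tsv(features, paths["features"], index_label="gene_id")
            _write_tsv(expression, paths["expression"], index_label="gene_id")
            _write_tsv(evidence, paths["evidence"], index_label="gene_id")
            _write_tsv(truth, paths["truth"], index_label="gene_id")
            record("simulate", paths, {"n_genes": int(len(features))})
        else:
            features = feature_table.read_feature_table(config.feature_table_path)
            expression = (feature_table.read_expression_matrix(config.expression_path)
                          if config.expression_path else None)
            evidence = pd.read_csv(config.evidence_path, sep="\t", index_col=0)
            evidence.index = evidence.index.astype(str)
            truth = (simulate.read_truth(config.truth_path)
                     if config.truth_path else None)

        # --- featurize ----------------------------------------------------
        if expression is not None and expression.shape[1] > 0:
            summaries = feature_table.summarize_expression(expression)
            features.loc[summaries.index, summaries.columns] = summaries
        features, removed = feature_table.drop_incomplete(features)
        p = outdir / "feature_table_complete.tsv"
        _write_tsv(features, p, index_label="gene_id")
        record("featurize", {"features": p}, {"n_removed": len(removed),
                                              "removed": removed})

        # --- categorize ---------------------------------------------------
        groups = categorize.assign_groups(evidence.loc[features.index])
        features = features.copy()
        features["group"] = groups
        summary = categorize.summarize_groups(evidence.loc[features.index], groups)
        p = outdir / "group_summary.tsv"
        _write_tsv(summary, p)
        record("categorize", {"group_summary": p},
               {"group_sizes": summary["n_genes"].to_dict()})

        # --- cluster ------------------------------------------------------
        Z = feature_table.standardize(features, config.feature_set)
        seed = manifest["seeds"]["cluster"]
        run = consensus.consensus_cluster(
            Z.to_numpy(), config.cluster_k, reps=config.cluster_reps,
            p_item=config.cluster_p_item, seed=seed)
        labels = consensus.final_clusters(run.consensus_matrix(), config.cluster_k)
        assignment = pd.Series(labels, index=Z.index, name="cluster")
        composition = consensus.cluster_composition(assignment, features["group"])
        pca_res = consensus.pca(Z.to_numpy())
        paths = {
            "clusters": outdir / "clusters.tsv",
            "composition": outdir / "cluster_composition.tsv",
            "pca_scores": outdir / "pca_scores.tsv",
            "pca_variance": outdir / "pca_variance.tsv",
        }
        _write_tsv(assignment.to_frame(), paths["clusters"], index_label="gene_id")
        _write_tsv(composition, paths["composition"], index_label="group")
        _write_tsv(pd.DataFrame(pca_res.scores[:, :2], index=Z.index,
                                columns=["PC1", "PC2"]),
                   paths["pca_scores"], index_label="gene_id")
        _write_tsv(pd.DataFrame(
            {"variance_fraction": pca_res.explained_variance_ratio}),
            paths["pca_variance"], index_label="component")
        record("cluster", paths,
               {"pc1_pct": float(100 * pca_res.explained_variance_ratio[0]),
                "pc2_pct": float(100 * pca_res.explained_variance_ratio[1])})

        # --- predict ------------------------------------------------------
        seed = manifest["seeds"]["predict"]
        active_ids = features.index[features["group"] == "I"].tolist()
        inactive_ids = features.index[features["group"] == "IV"].tolist()
        test_ids = features.index[features["group"].isin(["II", "III"])].tolist()
        pool = ensemble.build_pool(active_ids, inactive_ids,
                                   neg_ratio=config.neg_ratio, seed=seed)
        spec = ensemble.ClassifierSpec(kind=config.classifier)
        result = ensemble.run_ensemble(
            Z, pool, test_ids, spec, n_rounds=config.n_rounds,
            n_resamples=config.n_resamples,
            vote_threshold=config.vote_threshold,
            min_rounds=config.min_rounds, master_seed=seed,
            train_fraction=config.train_fraction)
        p = outdir / "predictions.tsv"
        _write_tsv(result.calls, p, index_label="gene_id")
        n_act = int((result.calls["final"] == "active").sum())
        n_inact = int((result.calls["final"] == "inactive").sum())
        record("predict", {"predictions": p},
               {"n_called_active": n_act, "n_called_inactive": n_inact,
                "n_abstained_fits": sum(r.n_abstained_fits for r in result.rounds)})

        # --- evaluate -----------------------------------------------------
        seed = manifest["seeds"]["evaluate"]
        metrics = evaluate.score_validation(result.rounds)
        called_active = result.calls.index[result.calls["final"] == "active"]
        called_inactive = result.calls.index[result.calls["final"] == "inactive"]
        controls = features.index[features["group"] == "II"]
        enr = evaluate.control_enrichment(controls, called_active, called_inactive)
        metrics_out = {
            "validation_accuracy": metrics.validation_accuracy,
            "false_negative_rate": metrics.false_negative_rate,
            "false_positive_rate": metrics.false_positive_rate,
            "n_called_active": n_act,
            "n_called_inactive": n_inact,
            "normalized_precision": evaluate.normalized_precision(
                metrics.validation_accuracy, n_act, n_inact),
            "control_fraction_in_active": enr.fraction_in_active,
            "control_fraction_in_inactive": enr.fraction_in_inactive,
            "control_enrichment_p": enr.p,
        }
        files = {}
        if len(called_active) and len(called_inactive) and len(active_ids):
            report = evaluate.verify_groups(
                features, called_active, called_inactive, active_ids, seed=seed)
            vp = outdir / "verification.tsv"
            _write_tsv(report, vp, index=False)
            files["verification"] = vp
        mp = outdir / "metrics.json"
        mp.write_text(json.dumps(metrics_out, indent=2, sort_keys=True) + "\n")
        files["metrics"] = mp
        record("evaluate", files, {"metrics": metrics_out})

        manifest["status"] = "complete"
    except Exception as exc:  # record partial state, then re-raise
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_report(manifest: dict | str | Path) -> str:
    """Human-readable run summary; every number traces to a stage artifact."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text())
    lines = ["famrank run report", "=" * 30,
             f"status: {manifest.get('status')}"]
    stages = manifest.get("stages", {})
    if "categorize" in stages:
        lines.append("group sizes: " + json.dumps(
            stages["categorize"].get("group_sizes", {}), sort_keys=True))
    if "cluster" in stages:
        st = stages["cluster"]
        lines.append(f"PC1/PC2 variance: {st.get('pc1_pct', float('nan')):.1f}% / "
                     f"{st.get('pc2_pct', float('nan')):.1f}%")
    if "predict" in stages:
        st = stages["predict"]
        n_act = st.get("n_called_active", 0)
        n_inact = st.get("n_called_inactive", 0)
        if n_act + n_inact == 0:
            lines.append("no consensus calls")
        else:
            lines.append(f"consensus calls: {n_act} active, {n_inact} inactive")
    if "evaluate" in stages:
        for k, v in sorted(stages["evaluate"].get("metrics", {}).items()):
            lines.append(f"{k}: {v}")
    if manifest.get("status") != "complete":
        lines.append(f"INCOMPLETE RUN; error: {manifest.get('error')}")
    return "\n".join(lines) + "\n"
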