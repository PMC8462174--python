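"""End-to-end pipeline orchestration with provenance logging.

``run_pipeline`` executes the full analysis from a YAML/JSON config:
trait cooccurrence scan -> Jaccard network -> modularity clusters ->
cluster abundance aggregation -> two-stage DistLM -> multifunctionality
network.  Every run writes a manifest recording the configuration, its
hash, the seed and the produced artifacts, plus a plain-text log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cooccurrence, distlm, multifunc, tables, traitnet

logger = logging.getLogger("mfnet")

REQUIRED_INPUTS = ("traits", "category_map", "abundance", "environment", "functions")


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineRun:
    """Paths of all artifacts produced by one pipeline execution."""

    config: tables.RunConfig
    out_dir: Path
    outputs: dict[str, Path] = field(default_factory=dict)
    log_path: Path | None = None


def config_hash(cfg: tables.RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config_path: str | Path) -> PipelineRun:
    raw = tables.load_config_mapping(config_path)
    inputs = raw.get("inputs", {})
    for key in REQUIRED_INPUTS:
        if key not in inputs:
            raise PipelineError("config", f"missing input field {key!r}")
        if not Path(inputs[key]).exists():
            raise PipelineError("config", f"input file for {key!r} not found: {inputs[key]}")
    cfg = tables.RunConfig.from_dict(raw.get("config", {}))
    out_dir = Path(raw.get("out_dir", "mfnet_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(config=cfg, out_dir=out_dir)
    run.log_path = out_dir / "run.log"
    handler = logging.FileHandler(run.log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest = {
        "config": cfg.to_dict(),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "status": "incomplete",
        "outputs": {},
    }
    manifest_path = out_dir / "manifest.json"
    try:
        logger.info("config: %s (hash %s)", cfg.to_dict(), manifest["config_hash"])

        stage = "read_inputs"
        category_map = tables.read_category_map(inputs["category_map"])
        traits = tables.read_fuzzy_traits(inputs["traits"], category_map)
        abundance = tables.read_sample_matrix(inputs["abundance"], "abundance")
        env = tables.read_sample_matrix(inputs["environment"], "environment")
        functions = tables.read_sample_matrix(inputs["functions"], "function")
        node_to_column = None
        if inputs.get("node_to_column"):
            df = pd.read_csv(inputs["node_to_column"])
            node_to_column = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        aliases = None
        if inputs.get("aliases"):
            df = pd.read_csv(inputs["aliases"])
            aliases = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))

        stage = "nat"
        binary = cooccurrence.binarize(traits, cfg.binarize_threshold)
        assocs = cooccurrence.cooccurrence_scan(binary, cfg.alpha, cfg.min_expected)
        scan_path = out_dir / "cooccurrence_scan.csv"
        cooccurrence.scan_to_frame(assocs).to_csv(scan_path, index=False)
        run.outputs["scan"] = scan_path
        net = traitnet.build_trait_network(assocs, binary.species_ids)
        net_path = out_dir / "trait_network.graphml"
        tables.write_network(net, net_path, "graphml")
        run.outputs["trait_network"] = net_path
        part = traitnet.detect_clusters(net, cfg.resolution, cfg.seed, cfg.louvain_restarts)
        logger.info("nat: %d significant pairs, %d clusters, Q=%.4f",
                    sum(a.significant for a in assocs),
                    len(set(part.cluster_of.values())), part.Q)

        stage = "aggregate"
        clusters = traitnet.aggregate_cluster_abundance(
            part, abundance, cfg.min_cluster_size, node_to_column)
        part_path = out_dir / "partition.csv"
        traitnet.partition_to_frame(part).to_csv(part_path, index=False)
        run.outputs["partition"] = part_path
        ca_path = out_dir / "cluster_abundance.csv"
        tables.write_sample_matrix(clusters.matrix, ca_path)
        run.outputs["cluster_abundance"] = ca_path

        stage = "distlm"
        report = distlm.run_two_stage(functions, clusters, env, cfg)
        report_path = out_dir / "distlm_report.json"
        report.to_json(report_path)
        run.outputs["report"] = report_path
        table_path = out_dir / "distlm_table.csv"
        report.to_table(aliases).to_csv(table_path)
        run.outputs["table"] = table_path
        for fname, res in report.results.items():
            logger.info("distlm %s: A=%.4f B=%.4f C=%.4f", fname,
                        res.r2_traits, res.r2_env_added, res.r2_total)

        stage = "assemble"
        mnet = multifunc.assemble(report, aliases)
        for fmt, suffix in (("gexf", ".gexf"), ("graphml", ".graphml"),
                            ("edge_csv", ".edges.csv")):
            path = out_dir / f"multifunc_network{suffix}"
            tables.write_network(mnet, path, fmt)
            run.outputs[f"multifunc_{fmt}"] = path
        summary_path = out_dir / "connectivity_summary.csv"
        multifunc.connectivity_summary(mnet).to_csv(summary_path, index=False)
        run.outputs["summary"] = summary_path

        manifest["status"] = "complete"
    except PipelineError:
        raise
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, str(exc)) from exc
    finally:
        manifest["outputs"] = {k: str(v) for k, v in run.outputs.items()}
        manifest_path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        logger.removeHandler(handler)
        handler.close()
    return run
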