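"""End-to-end pipeline: consensus -> ratio -> DE -> network -> risk.

One structured config (dict or YAML file) drives every stage; each run
writes its artifacts under one output directory and records them in a
manifest with SHA-256 content hashes, so reruns with the same seed and
parameters are byte-reproducible.  Inputs come either from a
``simulate`` block (the synthetic generator) or from user-supplied
tables; a stage is skipped when its output is supplied directly as an
input.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import cluster_and_report
from .config import ConfigError, SimConfig
from .consensus import CircConsensus
from .de import NBWaldDE, estimate_size_factors, normalize_expression
from .network import CeRnaNetworkBuilder
from .ratio import ratio_table
from .simulate import simulate_all
from .survival import CoxRiskScore

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineStageError", "load_config"]


class PipelineStageError(RuntimeError):
    """A stage failed; the failing stage is named in the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"pipeline config {path} is not a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


_INPUT_KEYS = (
    "samples", "circ_calls", "fsj_counts", "lnc_counts", "mrna_counts",
    "circ_mirna", "lnc_mirna", "mrna_mirna", "annotation",
    "consensus_matrix",
)


def _validate(config: dict) -> None:
    """Fail before any stage runs: file references and parameter ranges."""
    if "simulate" not in config and "inputs" not in config:
        raise ConfigError(
            "pipeline config needs a 'simulate' block or an 'inputs' block"
        )
    if "inputs" in config:
        inputs = config["inputs"]
        unknown = set(inputs) - set(_INPUT_KEYS)
        if unknown:
            raise ConfigError(f"unknown input keys: {sorted(unknown)}")
        required = {"samples", "lnc_counts", "mrna_counts"}
        missing_keys = required - set(inputs)
        if missing_keys:
            raise ConfigError(
                f"inputs block is missing required keys: "
                f"{sorted(missing_keys)}"
            )
        for key, p in inputs.items():
            if not Path(p).exists():
                raise ConfigError(f"input file for '{key}' not found: {p}")
    if "simulate" in config:
        SimConfig.from_dict(config["simulate"] or {})
    de_cfg = config.get("de", {})
    alpha = de_cfg.get("alpha", 0.1)
    if not 0 < alpha < 1:
        raise ConfigError(f"de.alpha must lie in (0, 1), got {alpha!r}")
    endpoint = config.get("risk", {}).get("endpoint", "os")
    if endpoint not in ("os", "pfs"):
        raise ConfigError(f"risk.endpoint must be 'os' or 'pfs', got "
                          f"{endpoint!r}")


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.manifest: dict = {"stages": []}

    def record(self, stage: str, params: dict, outputs: dict[str, Path]):
        self.manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "outputs": {
                    name: {"path": str(p), "sha256": _sha256(Path(p))}
                    for name, p in outputs.items()
                },
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    def write_tsv(self, name: str, df: pd.DataFrame, index: bool) -> Path:
        p = self.outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        return p

    def write_json(self, name: str, payload: dict) -> Path:
        p = self.outdir / f"{name}.json"
        p.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                default=_jsonable))
        return p


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: dict | str, outdir=None, seed: int | None = None
                 ) -> dict:
    """Run all stages from one config; returns the run manifest.

    ``config`` is a dict or a YAML path; ``outdir`` and ``seed``
    override the config's values.  A failing stage raises
    :class:`PipelineStageError` naming the stage; artifacts written by
    earlier stages are retained.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    config = dict(config)
    if seed is not None:
        config["seed"] = int(seed)
    if outdir is not None:
        config["outdir"] = str(outdir)
    if "outdir" not in config:
        raise ConfigError("pipeline config needs an 'outdir'")
    logging.basicConfig(
        level=getattr(logging, str(config.get("log_level", "INFO")).upper(),
                      logging.INFO)
    )
    _validate(config)
    out = Path(config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    run = _Run(out)
    run.manifest["config"] = config

    # ---- inputs -----------------------------------------------------
    consensus_direct = None
    annotation = None
    if "simulate" in config:
        sim_cfg = dict(config.get("simulate") or {})
        if "seed" in config:
            sim_cfg.setdefault("seed", int(config["seed"]))
        try:
            sim = simulate_all(SimConfig.from_dict(sim_cfg))
            paths = sim.write(out / "inputs")
        except Exception as e:  # pragma: no cover - config already validated
            raise PipelineStageError("simulate", e) from e
        run.record("simulate", sim_cfg,
                   {k: Path(v) for k, v in paths.items()})
        samples = sim.samples
        calls = sim.calls
        fsj = sim.fsj
        lnc_counts = sim.lnc_counts
        mrna_counts = sim.mrna_counts
        circ_mirna, lnc_mirna, mrna_mirna = (
            sim.circ_mirna, sim.lnc_mirna, sim.mrna_mirna,
        )
    else:
        inputs = config["inputs"]

        def read(key, index_col=None):
            if key not in inputs:
                return None
            return pd.read_csv(inputs[key], sep="\t", index_col=index_col)

        samples = read("samples")
        calls = read("circ_calls")
        fsj = read("fsj_counts", index_col=0)
        lnc_counts = read("lnc_counts", index_col=0)
        mrna_counts = read("mrna_counts", index_col=0)
        circ_mirna = read("circ_mirna")
        lnc_mirna = read("lnc_mirna")
        mrna_mirna = read("mrna_mirna")
        annotation = read("annotation")
        consensus_direct = read("consensus_matrix", index_col=0)

    groups = samples.set_index("sample_id")["response"]
    totals = samples.set_index("sample_id")["total_linear_mapped_reads"]
    size_factors = estimate_size_factors(totals)

    # ---- consensus --------------------------------------------------
    cons_params = dict(config.get("consensus", {}))
    if consensus_direct is not None:
        circ_matrix = consensus_direct
        logger.info("consensus stage skipped: matrix supplied directly")
    elif calls is not None and len(calls):
        try:
            cc = CircConsensus(**cons_params).fit(
                calls, sample_ids=list(samples["sample_id"])
            )
            circ_matrix = cc.matrix_
            keys = []
            for cid in cc.retained_keys_:
                chrom, span, strand = cid.rsplit(":", 2)
                s, e = span.rsplit("-", 1)
                keys.append((chrom, int(s), int(e), cid, 0, strand))
            retained = pd.DataFrame(
                keys,
                columns=["chrom", "start", "end", "name", "score", "strand"],
            )
            summaries = cc.summarize(annotation, groups)
            outputs = {
                "consensus_matrix": run.write_tsv("consensus_matrix",
                                                  circ_matrix, True),
                "retained_bed": run.write_tsv("retained_circ_bed6",
                                              retained, False),
                "per_chromosome": run.write_tsv(
                    "summary_per_chromosome", summaries["per_chromosome"],
                    False,
                ),
                "host_gene_ranking": run.write_tsv(
                    "summary_host_genes", summaries["host_gene_ranking"],
                    False,
                ),
            }
        except Exception as e:
            raise PipelineStageError("consensus", e) from e
        run.record("consensus", cons_params, outputs)
    else:
        raise PipelineStageError(
            "consensus", ValueError("no circRNA calls and no consensus "
                                    "matrix supplied")
        )

    # ---- ratio ------------------------------------------------------
    ratio_params = dict(config.get("ratio", {}))
    if fsj is not None:
        try:
            ratios = ratio_table(circ_matrix, fsj, groups=groups,
                                 by=ratio_params.get("by", "group"))
            p = run.write_tsv("circular_linear_ratio", ratios, True)
        except Exception as e:
            raise PipelineStageError("ratio", e) from e
        run.record("ratio", ratio_params, {"ratios": p})

    # ---- differential expression ------------------------------------
    de_params = dict(config.get("de", {}))
    de_results: dict[str, NBWaldDE] = {}
    try:
        for cls, mat in (("circ", circ_matrix), ("lnc", lnc_counts),
                         ("mrna", mrna_counts)):
            model = NBWaldDE(
                alpha=de_params.get("alpha", 0.1),
                lfc=de_params.get("lfc", 1.5),
                lfc_scale=de_params.get("lfc_scale", "log2"),
            ).fit(mat, groups.loc[mat.columns], size_factors=size_factors)
            de_results[cls] = model
        outputs = {
            f"de_{cls}": run.write_tsv(f"de_{cls}", m.results_, True)
            for cls, m in de_results.items()
        }
    except Exception as e:
        raise PipelineStageError("diff_expression", e) from e
    run.record("diff_expression", de_params, outputs)

    de_circ = de_results["circ"].significant_
    de_lnc = de_results["lnc"].significant_
    de_mrna = de_results["mrna"].significant_
    de_cerna = de_circ | de_lnc

    # ---- network ----------------------------------------------------
    net_params = dict(config.get("network", {}))
    edges = pd.DataFrame()
    if circ_mirna is not None and mrna_mirna is not None:
        try:
            cerna_expr = normalize_expression(
                pd.concat([circ_matrix, lnc_counts]), size_factors
            )
            mrna_expr = normalize_expression(mrna_counts, size_factors)
            net = CeRnaNetworkBuilder(
                min_tools=net_params.get("min_tools", 5),
                keep=net_params.get("keep", "positive"),
                r_min=net_params.get("r_min", 0.0),
            ).fit(
                circ_mirna,
                lnc_mirna if lnc_mirna is not None else circ_mirna.iloc[0:0],
                mrna_mirna,
                de_cerna,
                de_mrna,
                cerna_expression=cerna_expr,
                mrna_expression=mrna_expr,
            )
            edges = net.edges_
            graphml = out / "cerna_network.graphml"
            net.write_graphml(graphml)
            outputs = {
                "edges": run.write_tsv("cerna_edges", net.edge_table(),
                                       False),
                "graphml": graphml,
            }
        except Exception as e:
            raise PipelineStageError("cerna_network", e) from e
        run.record("cerna_network", net_params, outputs)

    # ---- survival risk ----------------------------------------------
    risk_params = dict(config.get("risk", {}))
    endpoint = risk_params.get("endpoint", "os")
    signature = sorted(de_cerna)
    if signature:
        try:
            sig_expr = normalize_expression(
                pd.concat([circ_matrix, lnc_counts]), size_factors
            ).loc[signature]
            t = samples.set_index("sample_id")[f"{endpoint}_time"]
            e = samples.set_index("sample_id")[f"{endpoint}_event"]
            model = CoxRiskScore(
                cutoff=risk_params.get("cutoff", "median")
            ).fit(sig_expr[t.index], t.to_numpy(), e.to_numpy())
            ev = model.evaluate(t.to_numpy(), e.to_numpy())
            km_rows = []
            for g, fit in ev["km"].items():
                surv = fit["survival"].copy()
                surv.insert(0, "group", g)
                km_rows.append(surv)
            km_table = pd.concat(km_rows, ignore_index=True)
            summary = {
                "endpoint": endpoint,
                "n_signature_features": len(signature),
                "cutoff": model.cutoff_,
                "logrank_statistic": ev["logrank_statistic"],
                "logrank_p": ev["logrank_p"],
                "medians": {
                    g: {"median": fit["median"],
                        "ci95": list(fit["median_ci"])}
                    for g, fit in ev["km"].items()
                },
            }
            outputs = {
                "coefficients": run.write_tsv(
                    "risk_coefficients",
                    pd.DataFrame({"coefficient": model.coef_,
                                  "se": model.se_,
                                  "flag": model.flags_}).rename_axis(
                                      "feature_id"),
                    True,
                ),
                "scores": run.write_tsv(
                    "risk_scores",
                    pd.DataFrame({"risk_score": model.risk_scores_,
                                  "risk_group": model.groups_}).rename_axis(
                                      "sample_id"),
                    True,
                ),
                "km_table": run.write_tsv("km_table", km_table, False),
                "summary": run.write_json("risk_summary", summary),
            }
        except Exception as e:
            raise PipelineStageError("survival_risk", e) from e
        run.record("survival_risk", risk_params, outputs)
    else:
        logger.warning("survival risk stage skipped: empty ceRNA signature")

    # ---- report -----------------------------------------------------
    try:
        sig_all = sorted(de_cerna)
        report_outputs = {}
        if len(sig_all) >= 2:
            mat = normalize_expression(
                pd.concat([circ_matrix, lnc_counts]), size_factors
            ).loc[sig_all]
            classes = pd.Series(
                ["circ" if f in set(circ_matrix.index) else "lnc"
                 for f in sig_all],
                index=sig_all,
            )
            rep = cluster_and_report(
                mat, groups=groups,
                up=de_results["circ"].up_ | de_results["lnc"].up_,
                down=de_results["circ"].down_ | de_results["lnc"].down_,
                feature_classes=classes,
            )
            report_outputs["heatmap_matrix"] = run.write_tsv(
                "heatmap_matrix", rep["heatmap"], True
            )
            report_outputs["de_summary"] = run.write_tsv(
                "de_summary", rep["summary"], False
            )
        counts_summary = pd.DataFrame(
            [
                {"class": cls, "n_tested":
                 int((m.results_["status"] == "tested").sum()),
                 "n_up": len(m.up_), "n_down": len(m.down_)}
                for cls, m in de_results.items()
            ]
        )
        report_outputs["class_counts"] = run.write_tsv(
            "de_class_counts", counts_summary, False
        )
        if len(edges):
            report_outputs["n_edges"] = run.write_json(
                "network_summary",
                {"n_edges": int(len(edges)),
                 "n_cernas": int(edges["cerna_id"].nunique()),
                 "n_mrnas": int(edges["mrna_id"].nunique())},
            )
    except Exception as e:
        raise PipelineStageError("report", e) from e
    run.record("report", {}, report_outputs)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(run.manifest, indent=2, sort_keys=True, default=_jsonable)
    )
    return run.manifest
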