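"""End-to-end orchestration: load -> metrics -> null ensemble -> rich club ->
modules -> enrichment -> report, with a reproducibility manifest.

Each stage writes its artifacts before the next begins, so a failed run
leaves the completed stages' outputs on disk. The manifest records the
package version, the resolved configuration, the seed and per-stage wall
times; config + seed fully determine every result artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from . import graph_metrics as gm
from . import mcl as mcl_mod
from . import net_io, richclub, synthetic
from . import enrichment as enr
from .nullmodels import NullEnsembleConfig, generate_ensemble

logger = logging.getLogger(__name__)

STAGES = ("metrics", "null", "richclub", "modules", "enrichment", "report")


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    edges: str | None = None
    annotations: str | None = None
    drug_targets: str | None = None
    synthetic_spec: synthetic.SyntheticSpec | None = None
    out_dir: str = "results"
    score_threshold: float = net_io.DEFAULT_SCORE_THRESHOLD
    null_kind: str = "degree_preserving"
    null_n: int = 1000
    null_swaps_per_edge: float = 10.0
    small_world_n_rand: int = 100
    core_threshold: float = 1.3
    plateau_threshold: float = 0.95
    core_rule: str = "min"
    inflation: float = 2.0
    min_module_size: int = 5
    background_size: int = 20000
    seed: int = 0
    skip: tuple = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["skip"] = sorted(self.skip)
        return d


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_all(config: RunConfig) -> dict:
    """Run every stage in fixed order; returns the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}
    manifest = {"package_version": __version__, "seed": config.seed,
                "config": config.to_dict(), "stages": {}}
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()

    # ---- load / generate -------------------------------------------------
    t0 = time.perf_counter()
    annotations = None
    drug_targets = None
    if config.edges:
        G = net_io.read_edge_list(config.edges, config.score_threshold)
        if config.annotations:
            annotations = net_io.read_annotations(config.annotations, network=G)
        if config.drug_targets:
            drug_targets = net_io.read_drug_targets(config.drug_targets)
    elif config.synthetic_spec is not None:
        data = synthetic.generate_dataset(config.synthetic_spec)
        G = data["graph"]
        annotations = data["annotations"]
        drug_targets = data["drug_targets"]
        _json_dump(data["ground_truth"], out / "ground_truth.json")
    else:
        raise ValueError("config needs either an edge list or a synthetic spec")
    bundle["graph"] = G
    net_io.write_results(out, graph=G)
    manifest["stages"]["load"] = round(time.perf_counter() - t0, 3)
    logger.info("network: %d nodes, %d edges", G.number_of_nodes(),
                G.number_of_edges())

    # ---- topology metrics ------------------------------------------------
    if "metrics" not in config.skip:
        t0 = time.perf_counter()
        dd = gm.degree_distribution(G)
        sw = gm.small_world_coefficient(G, n_rand=config.small_world_n_rand,
                                        seed=config.seed)
        bundle["degree_distribution"] = dd
        bundle["small_world"] = sw
        pd.DataFrame(sorted(dd.histogram.items()),
                     columns=["degree", "count"]).to_csv(
            out / "degree_distribution.tsv", sep="\t", index=False)
        metrics = {"n_nodes": G.number_of_nodes(),
                   "n_edges": G.number_of_edges(),
                   "mean_degree": dd.mean_degree,
                   "power_law_gamma": dd.fit.gamma if dd.fit else None,
                   "clustering_coefficient": sw.c_obs,
                   "characteristic_path_length": sw.l_obs,
                   "c_random": sw.c_rand, "l_random": sw.l_rand,
                   "small_world_sigma": sw.sigma}
        _json_dump(metrics, out / "metrics.json")
        manifest["stages"]["metrics"] = round(time.perf_counter() - t0, 3)

    # ---- null ensemble + rich club --------------------------------------
    if "richclub" not in config.skip:
        t0 = time.perf_counter()
        ens_cfg = NullEnsembleConfig(kind=config.null_kind,
                                     n_networks=config.null_n,
                                     swaps_per_edge=config.null_swaps_per_edge,
                                     seed=config.seed)
        ensemble = generate_ensemble(G, ens_cfg)
        manifest["stages"]["null"] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()
        profile = richclub.normalized_rho(G, ensemble)
        call = richclub.call_rich_club(profile,
                                       core_threshold=config.core_threshold,
                                       plateau_threshold=config.plateau_threshold,
                                       core_rule=config.core_rule)
        bundle["richclub_profile"] = profile
        bundle["richclub_call"] = call
        net_io.write_results(out, richclub_profile=profile.to_frame())
        call_out = {"detected": call.detected,
                    "significant_range": call.significant_range,
                    "peak_k": call.peak_k, "peak_rho": call.peak_rho,
                    "core_range": call.core_range,
                    "core_size": len(call.core_nodes),
                    "core_nodes": sorted(call.core_nodes, key=str),
                    "strongest_component_size": len(call.strongest_component_nodes),
                    "strongest_component_nodes":
                        sorted(call.strongest_component_nodes, key=str),
                    "overlap_nodes": sorted(call.overlap_nodes, key=str),
                    "flag": call.flag}
        if annotations is not None and call.detected and call.core_nodes:
            freq = net_io.annotations_to_frequency_map(annotations)
            try:
                fold, p = richclub.compare_frequency(call.core_nodes, freq)
                call_out["frequency_fold_club_vs_nonclub"] = fold
                call_out["frequency_welch_p"] = p
            except ValueError as exc:
                logger.warning("frequency comparison skipped: %s", exc)
        _json_dump(call_out, out / "richclub_call.json")
        manifest["stages"]["richclub"] = round(time.perf_counter() - t0, 3)

    # ---- modules ---------------------------------------------------------
    if "modules" not in config.skip:
        t0 = time.perf_counter()
        part = mcl_mod.mcl_cluster(G, inflation=config.inflation)
        part = mcl_mod.filter_modules(part, min_size=config.min_module_size)
        meta = mcl_mod.meta_network(G, part)
        bundle["modules"] = part
        bundle["meta_network"] = meta
        net_io.write_results(out, modules=part.to_frame())
        nx.write_graphml(meta.graph, out / "meta_network.graphml")
        rows = [(m, part.kept[m], part.module_sizes[m],
                 meta.module_degree.get(m, 0.0), meta.intra_edges.get(m, 0))
                for m in sorted(part.kept)]
        pd.DataFrame(rows, columns=["module", "size_rank", "size",
                                    "module_degree", "intra_edges"]).to_csv(
            out / "module_summary.tsv", sep="\t", index=False)
        manifest["stages"]["modules"] = round(time.perf_counter() - t0, 3)

    # ---- enrichment ------------------------------------------------------
    if "enrichment" not in config.skip and drug_targets:
        t0 = time.perf_counter()
        network_nodes = set(G.nodes())
        records = enr.drug_enrichment(drug_targets, network_nodes,
                                      background=config.background_size)
        rows = [dataclasses.asdict(r) | {"foreground": "network"}
                for r in records]
        call = bundle.get("richclub_call")
        if call is not None and call.detected and call.core_nodes:
            in_net = net_io.in_network_targets(drug_targets, G)
            rc_records = enr.drug_enrichment(in_net, set(call.core_nodes),
                                             background=network_nodes)
            rows += [dataclasses.asdict(r) | {"foreground": "richclub"}
                     for r in rc_records]
            deg_rows = []
            for drug, targets in sorted(in_net.items()):
                try:
                    mt, mn, p = enr.target_degree_comparison(G, targets)
                    deg_rows.append((drug, mt, mn, p))
                except ValueError:
                    continue
            pd.DataFrame(deg_rows, columns=["drug", "target_mean_degree",
                                            "nontarget_mean_degree",
                                            "welch_p"]).to_csv(
                out / "target_degree.tsv", sep="\t", index=False)
        df = pd.DataFrame(rows)
        bundle["enrichment"] = df
        net_io.write_results(out, enrichment=df)
        manifest["stages"]["enrichment"] = round(time.perf_counter() - t0, 3)

    # ---- report ----------------------------------------------------------
    if "report" not in config.skip:
        text = report(bundle)
        (out / "report.md").write_text(text)
        bundle["report"] = text
    summary = _summary(bundle)
    net_io.write_results(out, summary=summary)
    _json_dump(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def _summary(bundle: dict) -> dict:
    G = bundle["graph"]
    s: dict = {"n_nodes": G.number_of_nodes(), "n_edges": G.number_of_edges(),
               "seed": bundle["config"].seed}
    dd = bundle.get("degree_distribution")
    if dd is not None and dd.fit is not None:
        s["power_law_gamma"] = round(dd.fit.gamma, 6)
    sw = bundle.get("small_world")
    if sw is not None:
        s.update(clustering_coefficient=round(sw.c_obs, 6),
                 characteristic_path_length=round(sw.l_obs, 6),
                 small_world_sigma=round(sw.sigma, 6))
    call = bundle.get("richclub_call")
    if call is not None:
        s["richclub_detected"] = call.detected
        if call.detected:
            s.update(richclub_range=list(call.significant_range),
                     richclub_peak_k=call.peak_k,
                     richclub_peak_rho=round(call.peak_rho, 6),
                     richclub_core_size=len(call.core_nodes))
    part = bundle.get("modules")
    if part is not None:
        s["n_modules_kept"] = len(part.kept)
    df = bundle.get("enrichment")
    if df is not None and len(df):
        top = df.sort_values(["p_value", "set_name"]).iloc[0]
        s["top_enriched_drug"] = str(top["set_name"])
    return s


def report(bundle: dict) -> str:
    """One-page markdown summary drawn from the same objects as the artifacts."""
    s = _summary(bundle)
    lines = ["# Interactome analysis report", "",
             f"- Nodes: {s['n_nodes']}  |  Edges: {s['n_edges']}"]
    if "power_law_gamma" in s:
        lines.append(f"- Power-law exponent (MLE): {s['power_law_gamma']:.3g}")
    if "small_world_sigma" in s:
        lines.append(f"- Clustering coefficient: {s['clustering_coefficient']:.4g}"
                     f"  |  Path length: {s['characteristic_path_length']:.4g}"
                     f"  |  Small-world sigma: {s['small_world_sigma']:.3g}")
    call = bundle.get("richclub_call")
    if call is not None:
        if call.detected:
            lines.append(
                f"- Rich club: degrees {s['richclub_range'][0]}"
                f"-{s['richclub_range'][1]}, peak rho "
                f"{s['richclub_peak_rho']:.3g} at k = {s['richclub_peak_k']}; "
                f"core of {s['richclub_core_size']} nodes")
        else:
            lines.append("- Rich club: no rich-club detected")
    if "n_modules_kept" in s:
        lines.append(f"- Modules kept (size >= "
                     f"{bundle['config'].min_module_size}): {s['n_modules_kept']}")
    if "top_enriched_drug" in s:
        lines.append(f"- Top enriched drug: {s['top_enriched_drug']}")
    lines.append("")
    return "\n".join(lines)
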