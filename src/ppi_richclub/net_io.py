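"""Input/output for interaction networks, node annotations and drug-target tables.

The substrate of every analysis here is a simple undirected weighted graph of
protein accessions. Edge lists follow the STRING convention: one interaction
per line, ``protein_a  protein_b  combined_score`` with the score in [0, 1],
listed in either or both directions. Reading enforces simple-graph semantics:
self-loops are dropped (and counted), duplicate pairs keep the maximum score,
and edges below the score threshold are discarded.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

#: Default STRING combined-score cutoff for including an interaction.
DEFAULT_SCORE_THRESHOLD = 0.4


class EdgeListError(ValueError):
    """Raised for malformed or empty edge-list input."""


@dataclass
class NodeAnnotation:
    """Literature annotation for one accession.

    Parameters
    ----------
    accession : str
        Node identifier (raw accession string, case-sensitive).
    frequency : int
        Number of distinct literature reports mentioning the accession.
    labels : list of str
        Free-text pathway/category tags.
    orphan : bool
        True when the accession is absent from the network it annotates.
    """

    accession: str
    frequency: int
    labels: list[str] = field(default_factory=list)
    orphan: bool = False


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_edge_list(path: str | os.PathLike,
                   score_threshold: float = DEFAULT_SCORE_THRESHOLD) -> nx.Graph:
    """Read a STRING-style edge list into a simple undirected weighted graph.

    The file is whitespace- or tab-separated with at least three columns
    (node_a, node_b, combined_score). A header row is auto-detected by a
    non-numeric third field. Edges with score below ``score_threshold`` are
    discarded; duplicate pairs keep the maximum score; self-loops are dropped
    with a logged count.

    Returns
    -------
    networkx.Graph
        Graph with edge attribute ``weight`` holding the combined score.

    Raises
    ------
    EdgeListError
        On malformed lines, scores outside [0, 1], or an empty result.
    """
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError(f"score_threshold must be in [0, 1], got {score_threshold}")
    G = nx.Graph()
    n_self_loops = 0
    n_filtered = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split()
            if len(fields) < 3:
                raise EdgeListError(
                    f"{path}: line {lineno}: expected >= 3 columns, got {len(fields)}")
            a, b, score_str = fields[0], fields[1], fields[2]
            if lineno == 1 and not _is_number(score_str):
                continue  # header row
            if not _is_number(score_str):
                raise EdgeListError(
                    f"{path}: line {lineno}: non-numeric score {score_str!r}")
            score = float(score_str)
            if not 0.0 <= score <= 1.0:
                raise EdgeListError(
                    f"{path}: line {lineno}: score {score} outside [0, 1]")
            if a == b:
                n_self_loops += 1
                continue
            if score < score_threshold:
                n_filtered += 1
                continue
            if G.has_edge(a, b):
                if score > G[a][b]["weight"]:
                    G[a][b]["weight"] = score
            else:
                G.add_edge(a, b, weight=score)
    if n_self_loops:
        logger.info("dropped %d self-loop(s) from %s", n_self_loops, path)
    if n_filtered:
        logger.info("filtered %d edge(s) below score %.3g", n_filtered, score_threshold)
    if G.number_of_edges() == 0:
        raise EdgeListError(f"{path}: no edges pass threshold {score_threshold}")
    return G


def read_annotations(path: str | os.PathLike,
                     network: nx.Graph | None = None) -> list[NodeAnnotation]:
    """Read a node-annotation TSV (accession, frequency, optional labels).

    Labels are semicolon-separated in the third column. If ``network`` is
    given, accessions absent from it are retained but flagged as orphans.
    """
    records: list[NodeAnnotation] = []
    n_orphans = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if lineno == 1 and not _is_number(fields[1]):
                continue  # header
            accession = fields[0].strip()
            freq_str = fields[1].strip()
            try:
                frequency = int(freq_str)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: frequency {freq_str!r} is not an integer")
            if frequency < 0:
                raise ValueError(
                    f"{path}: line {lineno}: negative frequency {frequency}")
            labels = []
            if len(fields) >= 3 and fields[2].strip():
                labels = [t.strip() for t in fields[2].split(";") if t.strip()]
            orphan = network is not None and accession not in network
            if orphan:
                n_orphans += 1
            records.append(NodeAnnotation(accession, frequency, labels, orphan))
    if n_orphans:
        logger.info("%d annotation accession(s) not present in the network", n_orphans)
    return records


def annotations_to_frequency_map(records: Iterable[NodeAnnotation]) -> dict[str, int]:
    """Collapse annotation records to an accession -> frequency map."""
    return {r.accession: r.frequency for r in records}


def read_drug_targets(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a long-format drug-target TSV (drug, target_accession).

    Returns a map drug -> set of target accessions (duplicates collapsed).
    Raises ``ValueError`` on an empty file.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns (drug, target)")
            drug, target = fields[0].strip(), fields[1].strip()
            if lineno == 1 and drug.lower() in ("drug", "chemical"):
                continue  # header
            mapping.setdefault(drug, set()).add(target)
    if not mapping:
        raise ValueError(f"{path}: no drug-target rows found")
    return mapping


def in_network_targets(mapping: Mapping[str, set[str]],
                       network: nx.Graph) -> dict[str, set[str]]:
    """Restrict each drug's target set to accessions present in the network."""
    return {drug: {t for t in targets if t in network}
            for drug, targets in mapping.items()}


def write_edge_list(G: nx.Graph, path: str | os.PathLike) -> None:
    """Write the graph as a canonical TSV edge list (sorted pairs, sorted rows)."""
    rows = sorted((min(a, b), max(a, b), float(d.get("weight", 1.0)))
                  for a, b, d in G.edges(data=True))
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tcombined_score\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def write_results(out_dir: str | os.PathLike,
                  graph: nx.Graph | None = None,
                  richclub_profile: pd.DataFrame | None = None,
                  modules: pd.DataFrame | None = None,
                  enrichment: pd.DataFrame | None = None,
                  summary: Mapping | None = None) -> list[Path]:
    """Write result artifacts to ``out_dir`` in standard formats.

    The graph is written both as GraphML and as a TSV edge list; tables as
    TSV; the run summary (parameters, seed, headline statistics) as sorted
    JSON so that identical runs produce byte-identical files.

    Returns the list of files written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _table(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, sep="\t", index=False, float_format="%.10g")
        written.append(p)

    if graph is not None:
        p = out / "network.graphml"
        nx.write_graphml(graph, p)
        written.append(p)
        p = out / "network_edges.tsv"
        write_edge_list(graph, p)
        written.append(p)
    if richclub_profile is not None:
        _table(richclub_profile, "richclub_profile.tsv")
    if modules is not None:
        _table(modules, "modules.tsv")
    if enrichment is not None:
        _table(enrichment, "enrichment.tsv")
    if summary is not None:
        p = out / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)
    return written
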