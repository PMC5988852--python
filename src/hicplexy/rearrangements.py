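"""Breakpoint graphs, chained translocations, and deletion bridges.

Chromoplexy leaves a recognisable footprint: translocation junctions
whose breakpoints cluster on shared chromosomes, sometimes on the very
same restriction fragment, with copy-number losses ("deletion bridges")
spanning the gaps between consecutive breakpoints. The rearrangement
graph makes this explicit: nodes are breakpoints (breakpoints resolved
to the same fragment collapse into one node), junction edges join the
two partners of a translocation, and adjacency edges join breakpoints
on the same chromosome within a linking distance. Chains are connected
components containing at least two junctions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome import BreakpointRecord, GenomeError, GenomicInterval, chrom_sort_key

DEFAULT_LINK_DISTANCE = 2_000_000
DEFAULT_LOSS_LOG2 = -0.3
DEFAULT_ABUT_TOLERANCE = 250_000


@dataclass(frozen=True)
class CopyNumberSegment:
    chrom: str
    start: int
    end: int
    log2: float


@dataclass
class DeletionBridge:
    segment: CopyNumberSegment
    breakpoints: tuple[str, ...]  # node keys abutting either segment end
    distances: tuple[int, ...]


@dataclass
class Chain:
    translocations: tuple[str, ...]
    nodes: tuple[str, ...]
    chromosomes: tuple[str, ...]
    n_junctions: int
    bridges: tuple[DeletionBridge, ...] = ()


def read_copy_number_segments(path: str | Path) -> list[CopyNumberSegment]:
    """4-column TSV: chrom, start, end, log2 (BED-with-score also parses)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "log2"], usecols=[0, 1, 2, 3],
    )
    return [
        CopyNumberSegment(str(r.chrom), int(r.start), int(r.end), float(r.log2))
        for r in df.itertuples()
    ]


def _node_key(rec: BreakpointRecord) -> str:
    return f"{rec.chrom}:{rec.start}-{rec.end}"


def build_graph(
    records: Sequence[BreakpointRecord],
    link_distance: int = DEFAULT_LINK_DISTANCE,
) -> nx.MultiGraph:
    """Assemble the rearrangement graph from breakpoint records.

    Records with identical coordinates collapse into a single node (the
    shared-fragment case). Junction edges connect the two partners of
    each translocation id; adjacency edges connect same-chromosome nodes
    whose midpoints are within ``link_distance``.
    """
    g = nx.MultiGraph()
    for rec in records:
        key = _node_key(rec)
        if key in g:
            g.nodes[key]["partners"].append(rec.partner_id)
            g.nodes[key]["translocations"].add(rec.translocation_id)
        else:
            g.add_node(
                key,
                chrom=rec.chrom,
                start=rec.start,
                end=rec.end,
                midpoint=0.5 * (rec.start + rec.end),
                partners=[rec.partner_id],
                translocations={rec.translocation_id},
                single_fragment=rec.single_fragment,
            )

    by_tid: dict[str, list[str]] = {}
    for rec in records:
        by_tid.setdefault(rec.translocation_id, []).append(_node_key(rec))
    for tid, keys in sorted(by_tid.items()):
        if len(keys) != 2:
            continue
        a, b = keys
        if a == b:
            continue
        g.add_edge(a, b, kind="junction", translocation=tid)

    nodes = sorted(g.nodes, key=lambda k: (chrom_sort_key(g.nodes[k]["chrom"]),
                                           g.nodes[k]["start"]))
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            na, nb = g.nodes[a], g.nodes[b]
            if na["chrom"] != nb["chrom"]:
                continue
            if abs(na["midpoint"] - nb["midpoint"]) <= link_distance:
                g.add_edge(a, b, kind="adjacency")
    return g


def find_chains(graph: nx.MultiGraph) -> list[Chain]:
    """Connected components carrying >= 2 translocation junctions."""
    chains: list[Chain] = []
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        junctions = [
            d["translocation"]
            for _, _, d in sub.edges(data=True)
            if d["kind"] == "junction"
        ]
        if len(junctions) < 2:
            continue
        tids = sorted(
            {t for n in comp for t in graph.nodes[n]["translocations"]}
        )
        chroms = sorted(
            {graph.nodes[n]["chrom"] for n in comp}, key=chrom_sort_key
        )
        nodes = tuple(
            sorted(
                comp,
                key=lambda k: (
                    chrom_sort_key(graph.nodes[k]["chrom"]),
                    graph.nodes[k]["start"],
                ),
            )
        )
        chains.append(
            Chain(tuple(tids), nodes, tuple(chroms), len(junctions))
        )
    chains.sort(
        key=lambda c: (
            chrom_sort_key(graph.nodes[c.nodes[0]]["chrom"]),
            graph.nodes[c.nodes[0]]["start"],
        )
    )
    return chains


def component_map(graph: nx.MultiGraph) -> dict[str, int]:
    """Translocation id -> component index (junction+adjacency closure)."""
    out: dict[str, int] = {}
    for idx, comp in enumerate(
        sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    ):
        for node in comp:
            for tid in graph.nodes[node]["translocations"]:
                out.setdefault(tid, idx)
    return out


def annotate_deletion_bridges(
    graph: nx.MultiGraph,
    segments: Sequence[CopyNumberSegment],
    loss_log2_threshold: float = DEFAULT_LOSS_LOG2,
    abut_tolerance: int = DEFAULT_ABUT_TOLERANCE,
    known_chromosomes: set[str] | None = None,
) -> list[DeletionBridge]:
    """Attach copy-number losses whose ends abut breakpoints.

    A segment with log2 below the loss threshold becomes a bridge when a
    breakpoint-fragment midpoint lies within ``abut_tolerance`` of either
    segment end; both ends are treated symmetrically. Bridges are stored
    on the graph (``graph.graph['bridges']``) and on each abutting node.
    ``known_chromosomes`` (the genome's names), when given, validates the
    segment table.
    """
    bridges: list[DeletionBridge] = []
    for seg in segments:
        if known_chromosomes is not None and seg.chrom not in known_chromosomes:
            raise GenomeError(f"segment on unknown chromosome {seg.chrom!r}")
        if seg.log2 >= loss_log2_threshold:
            continue
        hits: list[tuple[str, int]] = []
        for node, data in graph.nodes(data=True):
            if data["chrom"] != seg.chrom:
                continue
            dist = min(
                abs(data["midpoint"] - seg.start),
                abs(data["midpoint"] - seg.end),
            )
            if dist <= abut_tolerance:
                hits.append((node, int(dist)))
        if hits:
            bridge = DeletionBridge(
                seg,
                tuple(h[0] for h in hits),
                tuple(h[1] for h in hits),
            )
            bridges.append(bridge)
            for node, _ in hits:
                graph.nodes[node].setdefault("bridges", []).append(bridge)
    graph.graph["bridges"] = bridges
    return bridges


def n_deletion_adjacent_breakpoints(graph: nx.MultiGraph) -> int:
    return sum(1 for _, d in graph.nodes(data=True) if d.get("bridges"))


def chains_to_json(chains: Sequence[Chain], path: str | Path) -> None:
    payload = [
        {
            "translocations": list(c.translocations),
            "nodes": list(c.nodes),
            "chromosomes": list(c.chromosomes),
            "n_junctions": c.n_junctions,
            "bridges": [
                {
                    "segment": vars(b.segment),
                    "breakpoints": list(b.breakpoints),
                    "distances": list(b.distances),
                }
                for b in c.bridges
            ],
        }
        for c in chains
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def junctions_to_links(
    graph: nx.MultiGraph, path: str | Path
) -> None:
    """Circos-style link text: one line per junction edge."""
    with open(path, "w") as fh:
        for a, b, d in graph.edges(data=True):
            if d["kind"] != "junction":
                continue
            na, nb = graph.nodes[a], graph.nodes[b]
            fh.write(
                f"{na['chrom']}\t{na['start']}\t{na['end']}\t"
                f"{nb['chrom']}\t{nb['start']}\t{nb['end']}\t"
                f"{d['translocation']}\n"
            )
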