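"""miRNA target scanning and tripartite regulatory-network assembly.

miRNA-target sites are scored with the classic plant-target penalty
scheme (ungapped: mismatch 1.0, G:U wobble 0.5, doubled in the 5'
core positions 2-13; sites kept at total penalty <= 3.0).  High-
confidence PPI edges (score >= 0.7), lncRNA target pairs and miRNA
sites are merged into one typed mRNA-lncRNA-miRNA network from which
seed-gene neighborhoods can be extracted (e.g. the Fra a sub-network
around the PR10 anthocyanin regulator).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .identify import reverse_complement
from .model import TargetPair, Transcript

MIRNA_MIN_LEN = 18
MIRNA_MAX_LEN = 26
MIRNA_EXPECTATION_CUTOFF = 3.0
#: 1-based miRNA positions whose penalties are doubled (5' core region).
CORE_START, CORE_END = 2, 13
PPI_CONFIDENCE_CUTOFF = 0.7

EDGE_TYPES = ("ppi", "mirna_target", "coexpression", "lnc_target")
NODE_TYPES = ("mRNA", "lncRNA", "miRNA")

#: Watson-Crick plus G:U wobble pairs in DNA alphabet (miRNA base, target
#: base): a miRNA G can pair a target T(U) and a miRNA T(U) a target G.
WOBBLE_PAIRS = {("G", "T"), ("T", "G")}
WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}


@dataclass(frozen=True)
class MirnaSite:
    mirna_id: str
    target_id: str
    target_start: int  # 0-based on the target transcript
    expectation: float
    alignment: str


def site_penalty(mirna_seq: str, site_seq: str) -> tuple[float, str]:
    """Penalty of an ungapped miRNA/site alignment plus a match string.

    ``site_seq`` is the target subsequence read 5'->3'; the miRNA 5' end
    pairs the 3' end of the site.  The match string is |/o/x (Watson-
    Crick / wobble / mismatch) ordered along the miRNA.
    """
    length = len(mirna_seq)
    if len(site_seq) != length:
        raise ValueError("site and miRNA lengths differ")
    total = 0.0
    marks = []
    for pos in range(1, length + 1):  # 1-based from miRNA 5' end
        m_base = mirna_seq[pos - 1]
        t_base = site_seq[length - pos]
        pair = (m_base, t_base)
        if pair in WC_PAIRS:
            penalty, mark = 0.0, "|"
        elif pair in WOBBLE_PAIRS:
            penalty, mark = 0.5, "o"
        else:
            penalty, mark = 1.0, "x"  # N never counts as a match
        if CORE_START <= pos <= CORE_END:
            penalty *= 2.0
        total += penalty
        marks.append(mark)
    return total, "".join(marks)


_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}


def _penalty_lookup(mirna_seq: str) -> "np.ndarray":
    """Per-site-position penalty table Q[j, base] for one miRNA.

    Site position j (0-based, 5'->3' on the target) pairs miRNA position
    p = L - j (1-based from the miRNA 5' end); Q folds in the core-region
    doubling so a site's total penalty is sum_j Q[j, site[j]].
    """
    length = len(mirna_seq)
    table = np.empty((length, 5))
    for j in range(length):
        pos = length - j  # 1-based miRNA position
        m_base = mirna_seq[pos - 1]
        weight = 2.0 if CORE_START <= pos <= CORE_END else 1.0
        for t_base, col in _BASE_INDEX.items():
            pair = (m_base, t_base)
            if pair in WC_PAIRS:
                penalty = 0.0
            elif pair in WOBBLE_PAIRS:
                penalty = 0.5
            else:
                penalty = 1.0
            table[j, col] = weight * penalty
    return table


def mirna_scan(
    mirnas: list[Transcript],
    transcripts: list[Transcript],
    cutoff: float = MIRNA_EXPECTATION_CUTOFF,
) -> list[MirnaSite]:
    """All miRNA target sites with total penalty <= cutoff.

    Every offset of every transcript is scored; qualifying sites carry
    their penalty and a |/o/x alignment string (match/wobble/mismatch
    along the miRNA from its 5' end).
    """
    encoded = {
        t.id: np.fromiter(
            (_BASE_INDEX[b] for b in t.sequence), dtype=np.intp,
            count=len(t.sequence),
        )
        for t in transcripts
    }
    sites: list[MirnaSite] = []
    for mirna in mirnas:
        length = len(mirna.sequence)
        if not MIRNA_MIN_LEN <= length <= MIRNA_MAX_LEN:
            raise ValueError(
                f"miRNA {mirna.id!r} length {length} outside "
                f"[{MIRNA_MIN_LEN}, {MIRNA_MAX_LEN}] nt"
            )
        lookup = _penalty_lookup(mirna.sequence)
        for target in transcripts:
            t_arr = encoded[target.id]
            n_offsets = len(t_arr) - length + 1
            if n_offsets <= 0:
                continue
            penalties = np.zeros(n_offsets)
            for j in range(length):
                penalties += lookup[j, t_arr[j : j + n_offsets]]
            for start in np.nonzero(penalties <= cutoff)[0]:
                total, marks = site_penalty(
                    mirna.sequence,
                    target.sequence[start : start + length],
                )
                sites.append(
                    MirnaSite(
                        mirna_id=mirna.id,
                        target_id=target.id,
                        target_start=int(start),
                        expectation=total,
                        alignment=marks,
                    )
                )
    return sites


def filter_ppi(edges: pd.DataFrame, cutoff: float = PPI_CONFIDENCE_CUTOFF) -> pd.DataFrame:
    """Keep protein-protein edges with confidence >= cutoff."""
    if len(edges) and (
        (edges["confidence"] < 0).any() or (edges["confidence"] > 1).any()
    ):
        raise ValueError("PPI confidences must lie in [0, 1]")
    return edges.loc[edges["confidence"] >= cutoff].reset_index(drop=True)


def normalize_string_scores(edges: pd.DataFrame) -> pd.DataFrame:
    """Rescale raw STRING 0-999 combined scores to [0, 1]."""
    out = edges.copy()
    out["confidence"] = out["confidence"] / 999.0
    return out


def assemble_network(
    ppi: pd.DataFrame | None = None,
    mirna_sites: list[MirnaSite] | None = None,
    lnc_target_pairs: list[TargetPair] | None = None,
    coexpr_edges: list[tuple[str, str, float]] | None = None,
    node_types: dict[str, str] | None = None,
) -> nx.MultiGraph:
    """Union of typed edges into one mRNA-lncRNA-miRNA network.

    ``node_types`` maps every node id to mRNA/lncRNA/miRNA; ids missing
    from the map raise.  Duplicate (pair, type) edges collapse keeping
    the maximum weight; the same pair may carry edges of several types.
    """
    node_types = node_types or {}
    graph = nx.MultiGraph()

    def add_edge(a: str, b: str, edge_type: str, weight: float, provenance: str):
        if a == b:
            return  # no self-loops
        for node in (a, b):
            if node not in node_types:
                raise ValueError(f"edge endpoint {node!r} has no declared type")
            graph.add_node(node, node_type=node_types[node])
        if graph.has_edge(a, b, key=edge_type):
            if weight > graph[a][b][edge_type]["weight"]:
                graph[a][b][edge_type]["weight"] = weight
                graph[a][b][edge_type]["provenance"] = provenance
        else:
            graph.add_edge(
                a, b, key=edge_type, edge_type=edge_type, weight=weight,
                provenance=provenance,
            )

    if ppi is not None:
        for row in ppi.itertuples(index=False):
            add_edge(row.node_a, row.node_b, "ppi", float(row.confidence), "ppi")
    for site in mirna_sites or []:
        add_edge(
            site.mirna_id, site.target_id, "mirna_target",
            -site.expectation, "mirna_scan",
        )
    for pair in lnc_target_pairs or []:
        weight = (
            abs(pair.correlation)
            if pair.correlation is not None
            else 1.0 / (1.0 + (pair.distance_bp or 0))
        )
        add_edge(
            pair.lncRNA_id, pair.gene_id, "lnc_target", weight,
            f"{pair.mode}_target",
        )
    for a, b, weight in coexpr_edges or []:
        add_edge(a, b, "coexpression", float(weight), "coexpression")
    return graph


def node_counts(graph: nx.MultiGraph) -> pd.DataFrame:
    counts: dict[str, int] = {t: 0 for t in NODE_TYPES}
    for _, data in graph.nodes(data=True):
        counts[data["node_type"]] = counts.get(data["node_type"], 0) + 1
    rows = [(t, n) for t, n in counts.items()]
    rows += [
        (f"edges_{et}", sum(1 for *_, k in graph.edges(keys=True) if k == et))
        for et in EDGE_TYPES
    ]
    return pd.DataFrame(rows, columns=["entity", "count"])


def extract_subnetwork(
    graph: nx.MultiGraph, seed_ids: list[str], k_hops: int = 1
) -> nx.MultiGraph:
    """Induced subgraph on seeds plus everything within k hops (any edge type)."""
    missing = [s for s in seed_ids if s not in graph]
    if missing:
        raise ValueError(f"seed ids not in network: {missing}")
    keep: set[str] = set()
    for seed in seed_ids:
        reach = nx.single_source_shortest_path_length(graph, seed, cutoff=k_hops)
        keep.update(reach)
    return graph.subgraph(keep).copy()


def edges_to_frame(graph: nx.MultiGraph) -> pd.DataFrame:
    rows = [
        (a, b, key, data["weight"], data["provenance"])
        for a, b, key, data in graph.edges(keys=True, data=True)
    ]
    frame = pd.DataFrame(
        rows, columns=["node_a", "node_b", "edge_type", "weight", "provenance"]
    )
    return frame.sort_values(["node_a", "node_b", "edge_type"]).reset_index(
        drop=True
    )


def write_graphml(graph: nx.MultiGraph, path: str) -> None:
    nx.write_graphml(graph, path)
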