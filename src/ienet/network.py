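"""Signed directed regulatory-network construction and graph statistics.

The network has one node per IE gene and one directed edge per significant
regulator -> target-promoter relationship, signed by the direction of the
effect and weighted by its magnitude.  Connectivity statistics (shortest
paths, normalized betweenness, the node-deletion perturbation scan) ignore
edge signs and self-loops: autoregulatory edges are stored, and counted in
degree summaries, but a self-loop is not a regulatory path between two
genes.  Feed-forward loop enumeration is sign-aware (default: activation
paths only) and likewise never uses self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx
import pandas as pd

from . import constants as C

__all__ = [
    "SignedEdge",
    "RegulatoryNetwork",
    "canonical_network",
    "build_network",
    "shortest_path_matrix",
    "normalized_betweenness",
    "degree_summary",
    "enumerate_ffls",
    "perturbation_scan",
    "network_report",
]


@dataclass(frozen=True)
class SignedEdge:
    regulator: str
    target: str
    sign: int          # +1 activation, -1 repression
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def is_auto(self) -> bool:
        return self.regulator == self.target


@dataclass
class RegulatoryNetwork:
    nodes: tuple[str, ...]
    edges: tuple[SignedEdge, ...]

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.regulator not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge endpoint not in node set: {e}")
            key = (e.regulator, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    def to_digraph(self, include_auto: bool = False) -> nx.DiGraph:
        """Unsigned networkx view; self-loops excluded unless requested."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if e.is_auto and not include_auto:
                continue
            g.add_edge(e.regulator, e.target, sign=e.sign, weight=e.weight)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.regulator, e.target, "+" if e.sign > 0 else "-", e.weight)
                for e in self.edges
            ],
            columns=["regulator", "target", "sign", "weight"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, nodes=None) -> "RegulatoryNetwork":
        edges = tuple(
            SignedEdge(
                r["regulator"],
                r["target"],
                +1 if str(r["sign"]) in ("+", "+1", "1", "positive") else -1,
                float(r.get("weight", 1.0)),
            )
            for _, r in df.iterrows()
        )
        if nodes is None:
            nodes = tuple(
                g for g in C.GENES
                if any(e.regulator == g or e.target == g for e in edges)
            ) or C.GENES
        return cls(tuple(nodes), edges)


def canonical_network() -> RegulatoryNetwork:
    """The reconstructed 5-gene, 15-edge signed IE regulatory network.

    Twelve positive relationships (eleven transactivations plus the ie2
    auto-activation) and three negative ones (negative autoregulation of ie0
    and pe38, repression of ie2 by ME53), weighted by the default effect
    magnitudes.
    """
    edges = tuple(
        SignedEdge(reg, tgt, sign, abs(C.REPORTER_INTERACTIONS[(tgt, reg.upper())]))
        for (reg, tgt), sign in C.CANONICAL_EDGE_SIGNS.items()
    )
    return RegulatoryNetwork(C.GENES, edges)


def build_network(
    calls: pd.DataFrame, nodes: tuple[str, ...] = C.GENES
) -> RegulatoryNetwork:
    """Assemble the signed network from classified reporter calls.

    One edge per row with ``call != "none"``; edge weight is the absolute
    interaction effect.  Rows for the empty-vector promoter are ignored.
    """
    edges = []
    for _, r in calls.iterrows():
        if r["call"] == "none" or r["promoter"] == C.EMPTY_VECTOR:
            continue
        edges.append(
            SignedEdge(
                C.DRIVER_TO_GENE.get(r["driver"], str(r["driver"]).lower()),
                r["promoter"],
                +1 if r["call"] == "positive" else -1,
                abs(float(r["effect_log10"])),
            )
        )
    return RegulatoryNetwork(tuple(nodes), tuple(edges))


def _distances(g: nx.DiGraph) -> dict[str, dict[str, int]]:
    return {s: nx.single_source_shortest_path_length(g, s) for s in g.nodes}


def shortest_path_matrix(net: RegulatoryNetwork):
    """All-pairs unweighted directed distances, signs and self-loops ignored.

    Returns ``(matrix, summary)``: a DataFrame of distances (NaN where the
    target is unreachable) and a summary dict with the mean over reachable
    ordered pairs of distinct nodes, the maximum finite distance and the pair
    attaining it, and the number of unreachable ordered pairs.
    """
    g = net.to_digraph()
    dist = _distances(g)
    nodes = list(net.nodes)
    mat = pd.DataFrame(float("nan"), index=nodes, columns=nodes)
    finite, max_pair, max_len, unreachable = [], None, -1, 0
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            d = dist[s].get(t)
            if d is None:
                unreachable += 1
                continue
            mat.loc[s, t] = d
            finite.append(d)
            if d > max_len:
                max_len, max_pair = d, (s, t)
    summary = {
        "n_ordered_pairs": len(nodes) * (len(nodes) - 1),
        "mean_shortest_path": sum(finite) / len(finite) if finite else float("nan"),
        "max_shortest_path": max_len if finite else float("nan"),
        "max_pair": max_pair,
        "unreachable_pairs": unreachable,
    }
    return mat, summary


def normalized_betweenness(net: RegulatoryNetwork) -> dict[str, float]:
    """Directed betweenness centrality normalized by (n-1)(n-2).

    betweenness(v) = sum over ordered pairs s != t (both != v) of the
    fraction of shortest s->t paths passing through v; unreachable pairs
    contribute zero.  Signs and self-loops are ignored.
    """
    g = net.to_digraph()
    return dict(nx.betweenness_centrality(g, normalized=True))


def degree_summary(net: RegulatoryNetwork):
    """Per-node degree table and the mean non-auto activating in-degree.

    The table reports total in/out degree (self-loops included and also
    broken out) plus the count of incoming non-auto activating edges, the
    statistic behind the "redundant stimulation" argument.
    """
    rows = []
    for v in net.nodes:
        in_all = sum(1 for e in net.edges if e.target == v)
        out_all = sum(1 for e in net.edges if e.regulator == v)
        auto = sum(1 for e in net.edges if e.is_auto and e.regulator == v)
        in_act = sum(
            1 for e in net.edges if e.target == v and e.sign > 0 and not e.is_auto
        )
        rows.append((v, in_all, out_all, auto, in_all - auto, out_all - auto, in_act))
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "in_degree", "out_degree", "auto",
            "in_nonauto", "out_nonauto", "in_activating_nonauto",
        ],
    )
    mean_act = float(df["in_activating_nonauto"].mean())
    return df, mean_act


def enumerate_ffls(
    net: RegulatoryNetwork, mode: str = "positive_only"
) -> list[tuple[str, str, str]]:
    """Exhaustively enumerate feed-forward loops (X, Y, Z): pairwise-distinct
    genes with edges X->Y, Y->Z and X->Z all present (and all positive in
    ``positive_only`` mode).  Self-loops never participate.
    """
    if mode not in ("positive_only", "any_sign"):
        raise ValueError("mode must be 'positive_only' or 'any_sign'")
    edges = {
        (e.regulator, e.target): e.sign for e in net.edges if not e.is_auto
    }
    if mode == "positive_only":
        edges = {k: s for k, s in edges.items() if s > 0}
    loops = []
    for x, y, z in permutations(net.nodes, 3):
        if (x, y) in edges and (y, z) in edges and (x, z) in edges:
            loops.append((x, y, z))
    return loops


@dataclass
class PerturbationResult:
    removed: str
    baseline: pd.DataFrame = field(repr=False)
    perturbed: pd.DataFrame = field(repr=False)
    changed_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_changed(self) -> int:
        return len(self.changed_pairs)


def perturbation_scan(net: RegulatoryNetwork):
    """Single-node deletion scan.

    For each gene: remove it and its edges, recompute shortest paths among
    the remaining ordered pairs, and record every pair whose distance
    differs from the full-network baseline — including pairs that become
    unreachable.  Returns ``(results, total_changed, total_comparisons)``
    with one :class:`PerturbationResult` per removal.
    """
    if len(net.nodes) < 3:
        raise ValueError("need >= 3 nodes")
    base_mat, _ = shortest_path_matrix(net)
    results = []
    total = 0
    for v in net.nodes:
        rest = tuple(n for n in net.nodes if n != v)
        sub = RegulatoryNetwork(
            rest,
            tuple(e for e in net.edges if v not in (e.regulator, e.target)),
        )
        pert_mat, _ = shortest_path_matrix(sub)
        changed = []
        for s in rest:
            for t in rest:
                if s == t:
                    continue
                b, p = base_mat.loc[s, t], pert_mat.loc[s, t]
                if (b != p) and not (pd.isna(b) and pd.isna(p)):
                    changed.append((s, t))
        results.append(
            PerturbationResult(v, base_mat.loc[list(rest), list(rest)], pert_mat, changed)
        )
        total += len(changed)
    n = len(net.nodes)
    return results, total, n * (n - 1) * (n - 2)


def network_report(net: RegulatoryNetwork) -> dict:
    """All headline statistics of a network in one JSON-serializable dict."""
    _, path_summary = shortest_path_matrix(net)
    degrees, mean_act = degree_summary(net)
    scan, changed, comparisons = perturbation_scan(net)
    ffls = enumerate_ffls(net)
    return {
        "n_nodes": len(net.nodes),
        "n_edges": len(net.edges),
        "n_positive_nonauto": sum(
            1 for e in net.edges if e.sign > 0 and not e.is_auto
        ),
        "n_auto": sum(1 for e in net.edges if e.is_auto),
        "shortest_paths": {
            **path_summary, "max_pair": list(path_summary["max_pair"] or []),
        },
        "normalized_betweenness": normalized_betweenness(net),
        "degrees": degrees.to_dict(orient="records"),
        "mean_activating_in_degree": mean_act,
        "ffls_positive_only": [list(t) for t in ffls],
        "perturbation": {
            "changed_pairs_total": changed,
            "comparisons_total": comparisons,
            "per_removal": {
                r.removed: [list(p) for p in r.changed_pairs] for r in scan
            },
        },
    }
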