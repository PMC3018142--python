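"""Interaction sub-network extraction, consistency scoring and fusion.

Query proteins are mapped to nodes of a scored interaction network (ordered
identifier lookup, then best similarity hit); a level-1 sub-network (the
seed plus its direct neighbours with all induced edges) is extracted per
seed and scored by the Ratio of consistency

    Rc = observed edges / (n * (n - 1) / 2),

the density of the induced sub-graph.  Two sub-networks A, B fuse when

    1 - (1 - Nc) * (1 - RcA) * (1 - RcB) >= score_threshold   and
    Nc = |A ∩ B| / min(|A|, |B|) >= nc_threshold,

applied greedily, highest fusion score first, recomputing after every
fusion until a fixpoint.  Rc of a sub-network with n <= 1 nodes is defined
as 1.0 (vacuously consistent), so a singleton contained in a neighbour
always fuses into it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

SIMILARITY_EVALUE_CUTOFF = 1e-5

ID_LEVELS = ("uniprot_id", "uniprot_ensembl", "refseq", "genome_reviews", "gene_name")


# ---------------------------------------------------------------------------
# mapping queries onto the network
# ---------------------------------------------------------------------------

@dataclass
class HomologMapping:
    """query id -> network node id with the method that produced it."""

    mapping: dict[str, str]
    method: dict[str, str]          # textual-id level or "similarity-best-hit"
    unmapped: list[str]
    warnings: list[str] = field(default_factory=list)


def map_to_network(
    queries: list[str],
    id_tables: dict[str, pd.DataFrame],
    similarity_hits: pd.DataFrame | None = None,
) -> HomologMapping:
    """Map queries by ordered identifier lookup, then by similarity.

    ``id_tables`` maps an identifier level (see :data:`ID_LEVELS`) to a
    two-column frame (query, node).  The first level with a *unique* match
    wins; an ambiguous match at a level falls through to the next with a
    warning.  Failing all levels, the best similarity hit with
    E <= 1e-05 from ``similarity_hits`` (columns query, node, evalue) is
    used; otherwise the query stays unmapped.
    """
    mapping: dict[str, str] = {}
    method: dict[str, str] = {}
    notes: list[str] = []
    lookup = {}
    for level, df in id_tables.items():
        if level not in ID_LEVELS:
            raise ValueError(f"unknown identifier level {level!r}")
        lookup[level] = df.groupby("query")["node"].apply(list).to_dict()
    sim: dict[str, tuple[float, str]] = {}
    if similarity_hits is not None and len(similarity_hits):
        ok = similarity_hits[similarity_hits["evalue"] <= SIMILARITY_EVALUE_CUTOFF]
        for q, grp in ok.groupby("query"):
            grp = grp.sort_values(["evalue", "node"], kind="mergesort")
            sim[q] = (float(grp.iloc[0]["evalue"]), str(grp.iloc[0]["node"]))
    unmapped = []
    for q in queries:
        hit = None
        for level in ID_LEVELS:
            nodes = lookup.get(level, {}).get(q)
            if not nodes:
                continue
            if len(set(nodes)) == 1:
                hit = (nodes[0], level)
                break
            notes.append(f"{q}: ambiguous {level} match, falling through")
        if hit is None and q in sim:
            hit = (sim[q][1], "similarity-best-hit")
        if hit is None:
            unmapped.append(q)
        else:
            mapping[q] = hit[0]
            method[q] = hit[1]
    return HomologMapping(mapping=mapping, method=method, unmapped=unmapped, warnings=notes)


# ---------------------------------------------------------------------------
# network construction and sub-network extraction
# ---------------------------------------------------------------------------

def build_network(edges: pd.DataFrame, cutoff: float = 0.9) -> nx.Graph:
    """Scored undirected network keeping edges with score >= cutoff.

    Duplicate undirected edges are collapsed to their maximum score;
    self-loops are rejected; nodes of sub-cutoff edges remain as isolated
    nodes.
    """
    g = nx.Graph()
    for row_no, (a, b, score) in enumerate(
        edges[["node_a", "node_b", "combined_score"]].itertuples(index=False),
        start=1,
    ):
        score = float(score)
        if not 0.0 <= score <= 1.0 or pd.isna(score):
            raise ValueError(f"malformed edge row {row_no}: score {score}")
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"malformed edge row {row_no}: self-loop on {a}")
        g.add_node(a)
        g.add_node(b)
        if score >= cutoff:
            prev = g.get_edge_data(a, b)
            if prev is None or prev["combined_score"] < score:
                g.add_edge(a, b, combined_score=score)
    return g


@dataclass(frozen=True)
class SubNetwork:
    """A node set with its induced edge count and consistency ratio."""

    nodes: frozenset[str]
    n_edges: int
    seeds: tuple[str, ...] = ()

    @property
    def rc(self) -> float:
        n = len(self.nodes)
        if n <= 1:
            return 1.0
        return self.n_edges / (n * (n - 1) / 2)

    @property
    def sort_key(self) -> tuple:
        return tuple(sorted(self.nodes))


def induced_subnetwork(
    graph: nx.Graph, nodes, seeds: tuple[str, ...] = ()
) -> SubNetwork:
    nodes = frozenset(nodes)
    n_edges = graph.subgraph(nodes).number_of_edges()
    return SubNetwork(nodes=nodes, n_edges=n_edges, seeds=tuple(sorted(seeds)))


def extract_subnetworks(graph: nx.Graph, seeds: list[str]) -> list[SubNetwork]:
    """One level-1 sub-network per seed: the seed plus its direct
    neighbours with all induced edges."""
    out = []
    for seed in seeds:
        if seed not in graph:
            raise ValueError(f"seed {seed!r} not in network")
        nodes = {seed} | set(graph.neighbors(seed))
        out.append(induced_subnetwork(graph, nodes, seeds=(seed,)))
    return out


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionParams:
    score_threshold: float = 0.7
    nc_threshold: float = 0.5


def nc(a: SubNetwork, b: SubNetwork) -> float:
    """Node consistency: shared nodes over the size of the smaller set."""
    if not a.nodes or not b.nodes:
        raise ValueError("Nc undefined for an empty sub-network")
    return len(a.nodes & b.nodes) / min(len(a.nodes), len(b.nodes))


def fusion_score(a: SubNetwork, b: SubNetwork) -> float:
    return 1.0 - (1.0 - nc(a, b)) * (1.0 - a.rc) * (1.0 - b.rc)


def should_fuse(
    a: SubNetwork, b: SubNetwork, params: FusionParams = FusionParams()
) -> tuple[bool, float]:
    """Both criteria must hold: fusion score >= 0.7 AND Nc >= 0.5."""
    score = fusion_score(a, b)
    ok = score >= params.score_threshold and nc(a, b) >= params.nc_threshold
    return ok, score


def fuse_all(
    subnets: list[SubNetwork],
    graph: nx.Graph,
    params: FusionParams = FusionParams(),
) -> list[SubNetwork]:
    """Greedy fusion to fixpoint.

    At each step every pair is evaluated and the fusable pair with the
    highest fusion score is merged (ties: larger Nc, then lexicographic
    node sets); the union's induced edges and Rc are recomputed.  The
    result is deterministic and independent of input order.
    """
    current = sorted(set(subnets), key=lambda s: s.sort_key)
    # identical node sets collapse immediately (Nc = 1 would fuse them)
    dedup: dict[frozenset, SubNetwork] = {}
    for s in current:
        if s.nodes in dedup:
            prev = dedup[s.nodes]
            dedup[s.nodes] = SubNetwork(
                nodes=s.nodes, n_edges=s.n_edges,
                seeds=tuple(sorted(set(prev.seeds) | set(s.seeds))),
            )
        else:
            dedup[s.nodes] = s
    current = sorted(dedup.values(), key=lambda s: s.sort_key)
    while len(current) > 1:
        best = None
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                a, b = current[i], current[j]
                ok, score = should_fuse(a, b, params)
                if not ok:
                    continue
                # maximize (score, Nc); break remaining ties by the smaller
                # lexicographic pair of node sets
                key = (-score, -nc(a, b), a.sort_key, b.sort_key)
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:
            break
        _key, i, j = best
        a, b = current[i], current[j]
        fused = induced_subnetwork(
            graph, a.nodes | b.nodes, seeds=tuple(sorted(set(a.seeds) | set(b.seeds)))
        )
        current = [s for k, s in enumerate(current) if k not in (i, j)]
        # a fusion producing an existing node set collapses with it
        current = [s for s in current if s.nodes != fused.nodes]
        current.append(fused)
        current.sort(key=lambda s: s.sort_key)
    return current


# ---------------------------------------------------------------------------
# coverage summaries
# ---------------------------------------------------------------------------

def coverage_summary(
    mapping: HomologMapping,
    subnets: list[SubNetwork],
    pathway_table: pd.DataFrame,
) -> dict:
    """Pathway and sub-network population statistics.

    ``pathway_table`` has columns (pathway, enzyme); enzymes repeated in a
    pathway count once.  A pathway is flagged when more than half of its
    distinct enzymes are covered by mapped queries; a sub-network is
    'populated' when it contains at least one mapped node.
    """
    mapped_nodes = set(mapping.mapping.values())
    per_pathway = []
    for pid, grp in pathway_table.groupby("pathway"):
        enzymes = set(grp["enzyme"])
        if not enzymes:
            import warnings

            warnings.warn(f"empty pathway {pid!r} excluded")
            continue
        covered = len(enzymes & mapped_nodes)
        frac = covered / len(enzymes)
        per_pathway.append(
            {
                "pathway": pid,
                "n_enzymes": len(enzymes),
                "n_covered": covered,
                "coverage": frac,
                "over_half": frac > 0.5,
            }
        )
    pathway_df = pd.DataFrame(
        per_pathway,
        columns=["pathway", "n_enzymes", "n_covered", "coverage", "over_half"],
    )
    populated = [bool(s.nodes & mapped_nodes) for s in subnets]
    n_queries = len(mapping.mapping) + len(mapping.unmapped)
    return {
        "pathways": pathway_df,
        "n_pathways": len(pathway_df),
        "n_pathways_over_half": int(pathway_df["over_half"].sum()) if len(pathway_df) else 0,
        "fraction_pathways_over_half": (
            float(pathway_df["over_half"].mean()) if len(pathway_df) else float("nan")
        ),
        "fraction_subnets_populated": (
            float(np.mean(populated)) if populated else float("nan")
        ),
        "mapping_rate": len(mapping.mapping) / n_queries if n_queries else float("nan"),
    }
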