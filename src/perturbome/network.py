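"""Assembly and characterisation of the perturbome network.

Drugs are nodes (flagged strong or weak by their perturbation strength
D_P); interaction calls contribute typed edges: directed positive or
negative edges pointing at the modulated drug, and undirected emergent
edges.  Directed edges are only admissible when the modulated drug is
strong -- a weak drug has no significant own effect whose modulation could
be detected -- which makes at most 1 edge type possible between two weak
drugs (emergent), 2 between a weak and a strong drug, and 3 between two
strong drugs.  The corresponding maximal link count

    M_max = w(w-1)/2 + 2ws + 3s(s-1)/2

(for s strong and w weak drugs) normalises the observed edge count into a
sparseness.  Core--periphery structure is detected with a minimal-residual
(MINRES) assignment against the idealized pattern in which edges exist
exactly among core pairs, scored for significance against
configuration-model null networks; robustness of the edge-type counts is
assessed by drug-label-swap randomization of the full calling pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .decomposition import Edge, InteractionCall

__all__ = [
    "PerturbomeNetwork",
    "CorePeripheryResult",
    "RandomizationResult",
    "assemble_perturbome",
    "max_possible_links",
    "max_links_between",
    "brute_force_max_links",
    "pair_count",
    "sparseness",
    "core_periphery",
    "degree_profiles",
    "write_sif",
    "write_graphml",
]

EDGE_TYPES = ("positive", "negative", "emergent")


@dataclass
class PerturbomeNetwork:
    """Typed multigraph of drug-perturbation interactions.

    ``strong`` maps drug -> bool.  ``edges`` hold at most one edge per
    admissible (pair, type, direction); rejected edges (directed at a weak
    drug) are kept for diagnostics.
    """

    strong: dict
    edges: list
    rejected: list = field(default_factory=list)

    @property
    def nodes(self) -> list:
        return sorted(self.strong)

    @property
    def n_strong(self) -> int:
        return sum(bool(v) for v in self.strong.values())

    @property
    def n_weak(self) -> int:
        return len(self.strong) - self.n_strong

    def counts_by_type(self) -> dict:
        out = {t: 0 for t in EDGE_TYPES}
        for e in self.edges:
            out[e.kind] += 1
        return out

    def to_networkx(self) -> nx.MultiDiGraph:
        """Directed multigraph; emergent edges carry ``directed=False``."""
        g = nx.MultiDiGraph()
        for node, strong in self.strong.items():
            g.add_node(node, strength="strong" if strong else "weak")
        for e in self.edges:
            g.add_edge(e.source, e.target, type=e.kind, directed=e.directed)
        return g

    def to_undirected_simple(self) -> nx.Graph:
        """Collapse all edge types onto a simple undirected graph."""
        g = nx.Graph()
        g.add_nodes_from(self.strong)
        for e in self.edges:
            g.add_edge(e.source, e.target)
        return g


def assemble_perturbome(
    calls: Iterable[InteractionCall],
    strong: Mapping[object, bool],
) -> PerturbomeNetwork:
    """Combine interaction calls into the perturbome network.

    Every valid drug becomes a node.  Directed edges whose target (the
    modulated drug) is weak are rejected with a diagnostic instead of
    being added; edges referencing a drug absent from ``strong`` raise.
    """
    strong = dict(strong)
    edges: list[Edge] = []
    rejected: list[tuple[Edge, str]] = []
    for call in calls:
        for e in call.edges:
            for node in (e.source, e.target):
                if node not in strong:
                    raise ValueError(f"edge references unknown drug {node!r}")
            if e.directed and not strong[e.target]:
                rejected.append((e, "directed edge at a weak drug"))
                continue
            edges.append(e)
    return PerturbomeNetwork(strong=strong, edges=edges, rejected=rejected)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def max_possible_links(s: int, w: int) -> int:
    """Maximal number of typed interaction links among s strong and w weak drugs."""
    if s < 0 or w < 0:
        raise ValueError("counts must be non-negative")
    return w * (w - 1) // 2 + 2 * w * s + 3 * s * (s - 1) // 2


def max_links_between(s1: int, w1: int, s2: int, w2: int) -> int:
    """Maximal typed links between two disjoint node groups."""
    return w1 * w2 + 2 * (s1 * w2 + w1 * s2) + 3 * s1 * s2


def brute_force_max_links(s: int, w: int) -> int:
    """Enumerate admissible typed edges over labelled nodes (oracle for M_max).

    Between two weak drugs only an emergent link is admissible; a
    weak--strong pair admits the emergent link plus a directed link toward
    the strong drug; a strong--strong pair admits emergent plus both
    directions.  A directed link may be positive or negative but occupies
    a single interaction slot, so each admissible (pair, slot) counts once.
    """
    nodes = [("s", i) for i in range(s)] + [("w", i) for i in range(w)]
    total = 0
    for u, v in itertools.combinations(nodes, 2):
        total += 1                       # emergent always possible
        if u[0] == "s":
            total += 1                   # v can modulate u
        if v[0] == "s":
            total += 1                   # u can modulate v
    return total


def pair_count(n: int) -> int:
    """Number of unordered pairs of n items."""
    return n * (n - 1) // 2


def sparseness(
    network: PerturbomeNetwork,
    core: set | None = None,
) -> dict:
    """Observed/maximal link ratio, optionally broken down by core membership.

    Returns overall sparseness and, when a core assignment is supplied,
    the within-core, within-periphery and core--periphery ratios with
    their own maximal counts.
    """
    s, w = network.n_strong, network.n_weak
    m_max = max_possible_links(s, w)
    out = {
        "n_edges": len(network.edges),
        "m_max": m_max,
        "sparseness": len(network.edges) / m_max if m_max else float("nan"),
    }
    if core is not None:
        periphery = set(network.strong) - set(core)
        s_c = sum(network.strong[n] for n in core)
        w_c = len(core) - s_c
        s_p = sum(network.strong[n] for n in periphery)
        w_p = len(periphery) - s_p
        in_core = in_per = between = 0
        for e in network.edges:
            u_core, v_core = e.source in core, e.target in core
            if u_core and v_core:
                in_core += 1
            elif not u_core and not v_core:
                in_per += 1
            else:
                between += 1
        for label, count, mmax in (
            ("core", in_core, max_possible_links(s_c, w_c)),
            ("periphery", in_per, max_possible_links(s_p, w_p)),
            ("between", between, max_links_between(s_c, w_c, s_p, w_p)),
        ):
            out[f"edges_{label}"] = count
            out[f"m_max_{label}"] = mmax
            out[f"sparseness_{label}"] = count / mmax if mmax else float("nan")
    return out


# ---------------------------------------------------------------------------
# core--periphery structure
# ---------------------------------------------------------------------------

@dataclass
class CorePeripheryResult:
    core: set
    periphery: set
    residual: float
    quality: float              # Pearson correlation of adjacency with the ideal pattern
    p_value: float
    n_null: int


def _minres_assign(graph: nx.Graph) -> tuple[list, float, float]:
    """Core set from the thresholded dominant singular vector.

    For an undirected graph the dominant singular vector of the adjacency
    equals the principal (Perron) eigenvector, whose entries score how
    strongly each node participates in the rank-1 core--periphery
    approximation A ~ w w^T.  Candidate cores are prefixes of the nodes
    ordered by score; the split maximizing the Pearson correlation
    between the adjacency and the idealized binary pattern (ties present
    exactly on pairs touching the core) is kept.  Graphs with no
    core--periphery contrast at any split (cliques, cycles) put every
    node in the core.

    Returns the core node list, the residual of the adjacency against
    the idealized pattern, and the pattern correlation (the quality used
    in the randomization test).
    """
    nodes = list(graph.nodes())
    n = len(nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    if n == 1:
        return nodes, 0.0, 0.0
    vals, vecs = np.linalg.eigh(adj)
    lead = np.abs(vecs[:, -1])          # Perron eigenvector, nonnegative
    order = np.argsort(-lead, kind="stable")
    iu = np.triu_indices(n, k=1)
    a_flat = adj[iu]

    def split_stats(k: int):
        mask = np.zeros(n, dtype=bool)
        mask[order[:k]] = True
        pattern = np.zeros_like(adj)
        pattern[mask, :] = 1.0
        pattern[:, mask] = 1.0
        p_flat = pattern[iu]
        residual = float(((a_flat - p_flat) ** 2).sum())
        if a_flat.std() == 0 or p_flat.std() == 0:
            return residual, 0.0
        return residual, float(np.corrcoef(a_flat, p_flat)[0, 1])

    best = None
    for k in range(1, n):
        residual, quality = split_stats(k)
        if best is None or quality > best[2]:
            best = (k, residual, quality)
    if best is None or best[2] <= 0.0:    # degenerate: no contrast (clique, cycle)
        k = n
        residual, quality = split_stats(k)
        best = (k, residual, quality)
    k, residual, quality = best
    core_nodes = [nodes[i] for i in order[:k]]
    return core_nodes, residual, quality


def core_periphery(
    graph: nx.Graph,
    n_null: int = 1000,
    seed: int | None = None,
) -> CorePeripheryResult:
    """MINRES core--periphery assignment with a configuration-model test.

    Nodes are scored by the dominant singular vector of the adjacency
    matrix and thresholded into a binary core/periphery assignment (see
    :func:`_minres_assign`).  Significance: the correlation quality
    between the adjacency and the idealized core--periphery pattern is
    recomputed on ``n_null`` degree-preserving configuration-model
    graphs; the p-value is the fraction of nulls scoring at least as
    high.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    graph = nx.Graph(graph)
    graph.remove_edges_from(nx.selfloop_edges(graph))
    core_nodes, residual, quality = _minres_assign(graph)

    rng = np.random.default_rng(seed)
    degrees = [d for _, d in graph.degree()]
    hits = 0
    for _ in range(n_null):
        null = nx.configuration_model(degrees, seed=int(rng.integers(2**31 - 1)))
        null = nx.Graph(null)
        null.remove_edges_from(nx.selfloop_edges(null))
        _, _, q_null = _minres_assign(null)
        if q_null >= quality:
            hits += 1
    p_value = (hits + 1) / (n_null + 1)
    core = set(core_nodes)
    return CorePeripheryResult(
        core=core,
        periphery=set(graph.nodes()) - core,
        residual=residual,
        quality=quality,
        p_value=p_value,
        n_null=n_null,
    )


# ---------------------------------------------------------------------------
# degrees, randomization summary, export
# ---------------------------------------------------------------------------

def degree_profiles(network: PerturbomeNetwork) -> pd.DataFrame:
    """Incoming, outgoing and emergent degree of every drug."""
    prof = pd.DataFrame(
        0,
        index=pd.Index(network.nodes, name="drug"),
        columns=["in_degree", "out_degree", "emergent_degree"],
    )
    for e in network.edges:
        if e.directed:
            prof.loc[e.source, "out_degree"] += 1
            prof.loc[e.target, "in_degree"] += 1
        else:
            prof.loc[e.source, "emergent_degree"] += 1
            prof.loc[e.target, "emergent_degree"] += 1
    prof["strength"] = [
        "strong" if network.strong[d] else "weak" for d in prof.index
    ]
    return prof


@dataclass
class RandomizationResult:
    """Observed versus label-swapped interaction counts.

    z = (observed - null mean) / null sd, per edge type; the null comes
    exclusively from rerunning the calling pipeline with swapped labels.
    """

    observed: dict
    null_mean: dict
    null_sd: dict
    z_scores: dict
    n_iterations: int
    null_counts: pd.DataFrame = None

    @classmethod
    def from_counts(cls, observed: dict, null_counts: pd.DataFrame) -> "RandomizationResult":
        if len(null_counts) < 2:
            raise ValueError("need at least 2 randomization iterations for a s.d.")
        mean = null_counts.mean().to_dict()
        sd = null_counts.std(ddof=1).to_dict()
        z = {
            k: (observed.get(k, 0) - mean[k]) / sd[k] if sd[k] > 0 else float("nan")
            for k in mean
        }
        return cls(
            observed=dict(observed),
            null_mean=mean,
            null_sd=sd,
            z_scores=z,
            n_iterations=len(null_counts),
            null_counts=null_counts,
        )


def write_sif(network: PerturbomeNetwork, path: str) -> None:
    """Simple-interaction-format export: source <type> target per line."""
    with open(path, "w") as fh:
        for e in network.edges:
            fh.write(f"{e.source}\t{e.kind}\t{e.target}\n")


def write_graphml(network: PerturbomeNetwork, path: str) -> None:
    nx.write_graphml(network.to_networkx(), path)
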