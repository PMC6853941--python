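"""Network-medicine metrics on a protein--protein interaction graph.

Drug target sets are mapped onto an undirected interactome and
characterised by where and how compactly they sit:

* module diameter <d_s>: mean shortest-path distance of each target to
  its nearest fellow target;
* Glass' Delta: effect size of <d_s> against a null of random node sets
  of the same size (Delta < -1 is conventionally read as strong
  localization);
* largest-connected-component (LCC) size of the target-induced subgraph
  and its z-score against the same null;
* separation s_AB = <d_AB> - (<d_AA> + <d_BB>)/2 between two target sets:
  negative values mean overlapping interactome neighborhoods, positive
  ones separated modules;
* mean and minimum cross-distances as auxiliary proximity measures;
* annotation-based similarity S(a, b) = 2 / min(n_i) over shared terms,
  scoring pairs by the most specific annotation they share;
* Tanimoto similarity on precomputed binary fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import pandas as pd

__all__ = [
    "LocalizationResult",
    "SeparationResult",
    "load_edge_list",
    "map_targets",
    "module_diameter",
    "lcc_size",
    "glass_delta",
    "separation",
    "annotation_similarity",
    "set_similarity",
    "tanimoto",
]


def load_edge_list(path: str, restrict_lcc: bool = True) -> nx.Graph:
    """Read a two-column TSV edge list into a simple undirected graph.

    Self-loops and duplicate edges are dropped; by default the graph is
    restricted to its largest connected component, mirroring the usual
    interactome convention.
    """
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v, *_ = line.split("\t")
            if u != v:
                g.add_edge(u, v)
    if restrict_lcc and g.number_of_nodes():
        lcc = max(nx.connected_components(g), key=len)
        g = g.subgraph(lcc).copy()
    return g


def map_targets(graph: nx.Graph, targets: Iterable) -> tuple[set, int]:
    """Intersect a target list with the graph; returns (mapped, n_dropped)."""
    targets = set(targets)
    mapped = targets & set(graph.nodes())
    return mapped, len(targets) - len(mapped)


def _distances_from(graph: nx.Graph, sources: Iterable) -> dict:
    return {s: nx.single_source_shortest_path_length(graph, s) for s in sources}


def module_diameter(
    graph: nx.Graph,
    targets: Iterable,
    _dist: Mapping | None = None,
) -> tuple[float, int]:
    """Mean nearest-neighbour distance <d_s> within a target set.

    For every target, the shortest-path distance to the closest *other*
    target of the same set; the mean over targets is the module diameter.
    Targets unreachable from all others (different component) have
    infinite d_s and are excluded from the mean with a warning; the count
    of exclusions is returned alongside.
    """
    targets = sorted(set(targets))
    if len(targets) < 2:
        raise ValueError("module diameter needs at least 2 mapped targets")
    dist = _dist or _distances_from(graph, targets)
    nearest = []
    n_excluded = 0
    for t in targets:
        d = min(
            (dist[t][u] for u in targets if u != t and u in dist[t]),
            default=np.inf,
        )
        if np.isinf(d):
            n_excluded += 1
        else:
            nearest.append(d)
    if n_excluded:
        warnings.warn(
            f"{n_excluded} target(s) unreachable from the rest of the module; "
            "excluded from <d_s>",
            stacklevel=2,
        )
    if not nearest:
        return float("nan"), n_excluded
    return float(np.mean(nearest)), n_excluded


def lcc_size(graph: nx.Graph, targets: Iterable) -> int:
    """Size of the largest connected component of the induced subgraph."""
    sub = graph.subgraph(set(targets))
    if sub.number_of_nodes() == 0:
        return 0
    return len(max(nx.connected_components(sub), key=len))


@dataclass
class LocalizationResult:
    ds_observed: float
    mu_random: float
    sigma_random: float
    glass_delta: float
    lcc_observed: int
    lcc_z: float
    n_random: int
    seed: int | None

    @property
    def strongly_localized(self) -> bool:
        """Conventional call: Glass' Delta < -1."""
        return self.glass_delta < -1.0


def _degree_bins(graph: nx.Graph, n_bins: int = 10) -> tuple[dict, list]:
    """Log-spaced degree bins; returns node->bin and bin->node-array."""
    degrees = dict(graph.degree())
    values = np.array(list(degrees.values()), dtype=float)
    edges = np.unique(
        np.percentile(values, np.linspace(0, 100, n_bins + 1))
    )
    node_bin = {
        n: int(np.searchsorted(edges[1:-1], d, side="right"))
        for n, d in degrees.items()
    }
    bins: dict[int, list] = {}
    for n, b in node_bin.items():
        bins.setdefault(b, []).append(n)
    return node_bin, bins


def glass_delta(
    graph: nx.Graph,
    targets: Iterable,
    n_random: int = 10_000,
    seed: int | None = None,
    degree_matched: bool = False,
) -> LocalizationResult:
    """Interactome localization of a target module as Glass' Delta.

    Samples ``n_random`` node sets of the same size (uniformly, or
    degree-binned when ``degree_matched``), computes the null
    distribution of module diameters, and returns
    Delta = (<d_s> - mu_random) / sigma_random, together with the LCC
    size of the module and its z-score against the same null.
    """
    targets = sorted(set(targets))
    nodes = np.array(sorted(graph.nodes()), dtype=object)
    if len(targets) >= len(nodes):
        raise ValueError("target set must be smaller than the graph")
    # one BFS per node of the (small) graph keeps sampling cheap
    all_dist = dict(nx.all_pairs_shortest_path_length(graph))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds_obs, _ = module_diameter(graph, targets, _dist=all_dist)
    lcc_obs = lcc_size(graph, targets)

    rng = np.random.default_rng(seed)
    size = len(targets)
    if degree_matched:
        node_bin, bins = _degree_bins(graph)
        bin_arrays = {b: np.array(v, dtype=object) for b, v in bins.items()}
        target_bins = [node_bin[t] for t in targets]

    null_ds = np.empty(n_random)
    null_lcc = np.empty(n_random)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_random):
            if degree_matched:
                sample: set = set()
                for b in target_bins:
                    pool = bin_arrays[b]
                    pick = pool[rng.integers(len(pool))]
                    while pick in sample:
                        pick = pool[rng.integers(len(pool))]
                    sample.add(pick)
                sample = sorted(sample)
            else:
                sample = list(nodes[rng.choice(len(nodes), size=size, replace=False)])
            null_ds[i], _ = module_diameter(graph, sample, _dist=all_dist)
            null_lcc[i] = lcc_size(graph, sample)

    mu = float(np.nanmean(null_ds))
    sigma = float(np.nanstd(null_ds, ddof=0))
    lcc_mu = float(null_lcc.mean())
    lcc_sd = float(null_lcc.std(ddof=0))
    return LocalizationResult(
        ds_observed=ds_obs,
        mu_random=mu,
        sigma_random=sigma,
        glass_delta=(ds_obs - mu) / sigma if sigma > 0 else float("nan"),
        lcc_observed=lcc_obs,
        lcc_z=(lcc_obs - lcc_mu) / lcc_sd if lcc_sd > 0 else float("nan"),
        n_random=n_random,
        seed=seed,
    )


@dataclass
class SeparationResult:
    d_aa: float
    d_bb: float
    d_ab: float
    s_ab: float
    d_mean_ab: float
    d_min_ab: float


def separation(graph: nx.Graph, targets_a: Iterable, targets_b: Iterable) -> SeparationResult:
    """Interactome separation s_AB between two target modules.

    <d_AB> averages, over every protein of either set, the shortest
    distance to the closest protein of the *other* set (shared proteins
    contribute 0); <d_AA>, <d_BB> are the module diameters.  Negative
    s_AB = <d_AB> - (<d_AA> + <d_BB>)/2 means the modules overlap.
    Also returns the all-cross-pairs mean distance and the minimal
    cross-pair distance.
    """
    a = sorted(set(targets_a))
    b = sorted(set(targets_b))
    if not a or not b:
        raise ValueError("both target sets need at least one mapped protein")
    dist = _distances_from(graph, set(a) | set(b))

    def nearest_cross(sources, others):
        vals = []
        for s in sources:
            d = 0 if s in others else min(
                (dist[s][o] for o in others if o in dist[s]), default=np.inf
            )
            vals.append(d)
        return vals

    others_b, others_a = set(b), set(a)
    cross = nearest_cross(a, others_b) + nearest_cross(b, others_a)
    finite = [v for v in cross if np.isfinite(v)]
    if len(finite) < len(cross):
        warnings.warn(
            f"{len(cross) - len(finite)} cross-component distance(s) excluded",
            stacklevel=2,
        )
    d_ab = float(np.mean(finite))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        d_aa = module_diameter(graph, a, _dist=dist)[0] if len(a) > 1 else 0.0
        d_bb = module_diameter(graph, b, _dist=dist)[0] if len(b) > 1 else 0.0

    pair_d = [dist[x][y] for x in a for y in b if y in dist[x]]
    d_mean = float(np.mean(pair_d)) if pair_d else float("nan")
    d_min = float(np.min(pair_d)) if pair_d else float("nan")
    return SeparationResult(
        d_aa=d_aa,
        d_bb=d_bb,
        d_ab=d_ab,
        s_ab=d_ab - (d_aa + d_bb) / 2.0,
        d_mean_ab=d_mean,
        d_min_ab=d_min,
    )


# ---------------------------------------------------------------------------
# annotation similarity and fingerprints
# ---------------------------------------------------------------------------

def _protein_terms(annotations: Mapping[object, set]) -> dict:
    index: dict = {}
    for term, proteins in annotations.items():
        for p in proteins:
            index.setdefault(p, set()).add(term)
    return index


def annotation_similarity(
    annotations: Mapping[object, set],
    a: object,
    b: object,
    _index: Mapping | None = None,
) -> float:
    """Similarity of two proteins from their most specific shared term.

    S(a, b) = 2 / n_i where n_i is the size (number of annotated
    proteins) of the smallest term both share; 0 when they share no term.
    Proteins absent from the annotation table count as annotation-free.
    """
    index = _index if _index is not None else _protein_terms(annotations)
    shared = index.get(a, set()) & index.get(b, set())
    if not shared:
        return 0.0
    n_min = min(len(annotations[t]) for t in shared)
    return 2.0 / n_min


def set_similarity(annotations: Mapping[object, set], proteins: Sequence) -> float:
    """Mean pairwise S(a, b) over all unordered pairs of a protein set."""
    proteins = sorted(set(proteins))
    if len(proteins) < 2:
        raise ValueError("set similarity needs at least 2 proteins")
    index = _protein_terms(annotations)
    sims = [
        annotation_similarity(annotations, a, b, _index=index)
        for i, a in enumerate(proteins)
        for b in proteins[i + 1:]
    ]
    return float(np.mean(sims))


def tanimoto(fp_a: str, fp_b: str) -> float:
    """Tanimoto coefficient of two equal-length binary fingerprints.

    |intersection| / |union| of the set bits; two all-zero fingerprints
    score 0 by convention.
    """
    if len(fp_a) != len(fp_b):
        raise ValueError("fingerprints must have equal length")
    a = np.frombuffer(fp_a.encode(), dtype=np.uint8) == ord("1")
    b = np.frombuffer(fp_b.encode(), dtype=np.uint8) == ord("1")
    union = int(np.sum(a | b))
    if union == 0:
        return 0.0
    return float(np.sum(a & b) / union)
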