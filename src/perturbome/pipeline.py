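"""End-to-end orchestration: raw cell table to perturbome network.

The stages are deliberately thin wrappers around the module functions so
each can also be run (and tested) in isolation:

    cells -> aggregate -> polish -> scale          (normalize)
          -> displacement vectors, D_P strength    (vectors)
          -> decomposition, D_I, thresholds, calls (decomposition)
          -> perturbome network                    (network)

The label-swap randomization reruns the calling stage with globally
permuted single-drug labels (never mapping a combination onto its own
constituents) and summarises per-type edge counts into z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import decomposition as dc
from . import network as net
from .normalize import (
    NormalizeConfig,
    WellFeatureTable,
    aggregate_wells,
    filter_features,
    filter_perturbations,
    polish,
    scale_unit_interval,
)
from ._mahalanobis import pca_basis
from .vectors import VectorSet, compute_vectors, perturbation_strength

__all__ = [
    "InteractionParams",
    "ScreenResult",
    "preprocess",
    "call_interactions",
    "run_screen",
    "randomize_interactions",
]


@dataclass
class InteractionParams:
    """Knobs of the interaction-calling stage."""

    di_cutoff: float = 3.0
    mad_k: float = 2.0
    variance_target: float = 0.90
    dp_cutoff: float = 7.0
    cloud_mode: str = "multiplicative"
    # drug-specific MAD bands need a dozen non-significant pairs to be
    # stable; drugs below this use the pooled global thresholds
    min_nonsig_pairs: int = 12


def preprocess(
    cells: pd.DataFrame,
    meta: pd.DataFrame,
    config: NormalizeConfig | None = None,
) -> WellFeatureTable:
    """Aggregate, polish and scale a raw per-cell table."""
    config = config or NormalizeConfig()
    wells = aggregate_wells(cells, meta)
    wells = polish(wells)
    return scale_unit_interval(wells, config.clip_lower_pct, config.clip_upper_pct)


def _pair_cloud(vecset: VectorSet, pair: tuple, vec_a, vec_b, combo, params: InteractionParams) -> dc.NICloud:
    plate = combo.plates[0]
    return dc.build_ni_cloud(
        vec_a.replicates,
        vec_b.replicates,
        vecset.plate_controls[plate],
        vecset.plate_control_median[plate],
        mode=params.cloud_mode,
    )


def screen_basis(vecset: VectorSet, variance_target: float = 0.90) -> np.ndarray:
    """Principal components of all treatment vectors of the screen.

    Noise reduction for D_I happens in the directions where treatments
    vary overall (explaining ``variance_target`` of that variance), not
    in a per-pair basis: a deviation is then never discarded merely
    because one pair's non-interaction cloud is flat along it.
    """
    stacks = [v.replicates for v in vecset.singles.values()]
    stacks += [v.replicates for v in vecset.combinations.values()]
    return pca_basis(np.vstack(stacks), variance_target)[0]


def call_interactions(
    vecset: VectorSet,
    params: InteractionParams | None = None,
) -> tuple[list, dict]:
    """Decompose, test and classify every measured combination.

    Returns the interaction calls and the per-drug effect-size
    thresholds derived from the non-significant pairs.
    """
    params = params or InteractionParams()
    records = []
    for pair, combo in vecset.combinations.items():
        a_name, b_name = pair
        if a_name not in vecset.singles or b_name not in vecset.singles:
            continue
        vec_a = vecset.singles[a_name]
        vec_b = vecset.singles[b_name]
        dec = dc.decompose(vec_a.mean, vec_b.mean, combo.mean)
        cloud = _pair_cloud(vecset, pair, vec_a, vec_b, combo, params)
        d_i, _, _ = dc.interaction_significance(
            combo.mean, cloud, params.variance_target, params.di_cutoff
        )
        records.append((pair, dec, d_i))

    nonsig: dict = {}
    for pair, dec, d_i in records:
        if d_i <= params.di_cutoff:
            a_name, b_name = pair
            nonsig.setdefault(a_name, []).append((dec.alpha, dec.beta, dec.gamma))
            nonsig.setdefault(b_name, []).append((dec.beta, dec.alpha, dec.gamma))
    thresholds = dc.derive_effect_thresholds(
        nonsig, mad_k=params.mad_k, min_pairs=params.min_nonsig_pairs
    )
    global_thr = thresholds["__global__"]

    calls = []
    for pair, dec, d_i in records:
        a_name, b_name = pair
        calls.append(
            dc.classify(
                pair, dec, d_i,
                thresholds.get(a_name, global_thr),
                thresholds.get(b_name, global_thr),
                di_cutoff=params.di_cutoff,
            )
        )
    return calls, thresholds


@dataclass
class ScreenResult:
    wells: WellFeatureTable
    vectors: VectorSet
    strength: dict
    calls: list
    thresholds: dict
    network: net.PerturbomeNetwork
    feature_selection: object = None
    validity: object = None


def run_screen(
    cells: pd.DataFrame,
    meta: pd.DataFrame,
    config: NormalizeConfig | None = None,
    params: InteractionParams | None = None,
    select_features: bool = False,
) -> ScreenResult:
    """Full pipeline from a raw cell table to the perturbome network.

    Feature selection is optional: synthetic screens usually plant only
    informative features, whereas real screens should enable it.
    """
    config = config or NormalizeConfig()
    params = params or InteractionParams()
    wells = preprocess(cells, meta, config)

    validity = filter_perturbations(wells, config)
    selection = None
    features = None
    if select_features:
        selection = filter_features(wells, config)
        features = selection.retained

    vecset = compute_vectors(wells, features=features, valid_wells=validity.wells["valid"])
    # drop singles from drugs that failed validity
    invalid = set(validity.drugs.index[~validity.drugs["valid"]])
    vecset.singles = {k: v for k, v in vecset.singles.items() if k not in invalid}

    strength = perturbation_strength(
        vecset.singles, vecset.controls,
        variance_target=params.variance_target, cutoff=params.dp_cutoff,
    )
    calls, thresholds = call_interactions(vecset, params)
    strong_flags = {k: strength[k].strong for k in vecset.singles}
    network = net.assemble_perturbome(
        [c for c in calls if c.is_interaction], strong_flags
    )
    return ScreenResult(
        wells=wells, vectors=vecset, strength=strength,
        calls=calls, thresholds=thresholds, network=network,
        feature_selection=selection, validity=validity,
    )


# ---------------------------------------------------------------------------
# label-swap randomization
# ---------------------------------------------------------------------------

def _constrained_derangement(drugs: list, pairs: list, rng: np.random.Generator,
                             max_swaps: int = 100_000) -> dict:
    """Permutation of drug labels valid for every combination.

    The requirement "a combination AB is decomposed against singles C, D
    outside {A, B}" is equivalent to a per-drug constraint: a drug's new
    label may be neither itself nor any of its combination partners.  A
    random permutation is repaired by swapping the targets of violating
    drugs with random other drugs until no violation remains.
    """
    n = len(drugs)
    forbidden = {x: {x} for x in drugs}
    for a, b in pairs:
        forbidden[a].add(b)
        forbidden[b].add(a)
    if any(len(f) >= n for f in forbidden.values()):
        raise RuntimeError("a drug is paired with every other drug; no valid permutation")
    perm = list(rng.permutation(n))
    for _ in range(max_swaps):
        violators = [i for i in range(n) if drugs[perm[i]] in forbidden[drugs[i]]]
        if not violators:
            return {drugs[i]: drugs[perm[i]] for i in range(n)}
        i = violators[int(rng.integers(len(violators)))]
        j = int(rng.integers(n - 1))
        j = j + 1 if j >= i else j
        # swap only if it does not break j's constraint worse than it helps
        perm[i], perm[j] = perm[j], perm[i]
    raise RuntimeError("could not repair the label permutation")


def randomize_interactions(
    vecset: VectorSet,
    thresholds: Mapping,
    params: InteractionParams | None = None,
    n_iter: int = 100,
    seed: int | None = None,
) -> net.RandomizationResult:
    """Null distribution of edge-type counts under drug-label swapping.

    Each iteration draws one global label permutation (constrained so no
    combination meets its own singles), reruns decomposition, D_I and
    classification with the *original* thresholds, and accumulates the
    per-type edge counts.  Same seed, same nulls.
    """
    if n_iter < 2:
        raise ValueError("need at least 2 iterations for a null s.d.")
    params = params or InteractionParams()
    rng = np.random.default_rng(seed)
    drugs = sorted(vecset.singles)
    pairs = [p for p in vecset.combinations if
             p[0] in vecset.singles and p[1] in vecset.singles]
    global_thr = thresholds["__global__"]

    def count_edges(calls):
        counts = {t: 0 for t in net.EDGE_TYPES}
        for call in calls:
            for e in call.edges:
                counts[e.kind] += 1
        return counts

    # observed counts with the true labelling
    observed_calls = []
    for pair in pairs:
        vec_a, vec_b = vecset.singles[pair[0]], vecset.singles[pair[1]]
        combo = vecset.combinations[pair]
        dec = dc.decompose(vec_a.mean, vec_b.mean, combo.mean)
        cloud = _pair_cloud(vecset, pair, vec_a, vec_b, combo, params)
        d_i, _, _ = dc.interaction_significance(
            combo.mean, cloud, params.variance_target, params.di_cutoff
        )
        observed_calls.append(
            dc.classify(pair, dec, d_i,
                        thresholds.get(pair[0], global_thr),
                        thresholds.get(pair[1], global_thr),
                        di_cutoff=params.di_cutoff)
        )
    observed = count_edges(observed_calls)

    null_rows = []
    for _ in range(n_iter):
        mapping = _constrained_derangement(drugs, pairs, rng)
        calls = []
        for pair in pairs:
            a_sub, b_sub = mapping[pair[0]], mapping[pair[1]]
            vec_a, vec_b = vecset.singles[a_sub], vecset.singles[b_sub]
            combo = vecset.combinations[pair]
            dec = dc.decompose(vec_a.mean, vec_b.mean, combo.mean)
            cloud = _pair_cloud(vecset, pair, vec_a, vec_b, combo, params)
            d_i, _, _ = dc.interaction_significance(
                combo.mean, cloud, params.variance_target, params.di_cutoff
            )
            calls.append(
                dc.classify(pair, dec, d_i,
                            thresholds.get(a_sub, global_thr),
                            thresholds.get(b_sub, global_thr),
                            di_cutoff=params.di_cutoff)
            )
        null_rows.append(count_edges(calls))
    null_counts = pd.DataFrame(null_rows)
    return net.RandomizationResult.from_counts(observed, null_counts)
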