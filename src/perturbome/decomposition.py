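"""Geometric decomposition of pairwise perturbation interactions.

Two single-perturbation vectors a and b span a plane S containing the
non-interaction (NI) point a + b: if the perturbations do not interfere,
their combination is the superposition of the individual effects.  Any
measured combination vector c decomposes uniquely as

    c = alpha * a + beta * b + gamma * n_hat,

where (alpha, beta) are the least-squares in-plane coefficients (obtained
from the 2x2 normal equations of the distance minimisation to S), n_hat is
the unit residual direction perpendicular to both a and b, and gamma >= 0
is the magnitude of the emergent, out-of-plane component.  Deviations of
(alpha, beta) from 1 mean that one drug's contribution was stretched or
shrunk by the other; gamma > 0 means the combination shows a phenotype
attributable to neither drug alone.

Sign patterns of (alpha - 1, beta - 1, gamma) over {-, 0, +} partition the
state space into 27 subspaces; because both signs of gamma describe the
same emergent phenotype they merge into 18 interaction classes: 2
undirected, 8 uni-directional and 8 bi-directional.

Statistical calling works against a *non-interaction cloud*: all pairwise
sums of the two drugs' replicate vectors, each perturbed by the control
variation of the combination's plate.  The Mahalanobis distance D_I of the
observed combination from this cloud (in a PCA-reduced space) measures how
unlikely the deviation is under no interaction; effect sizes are gated by
drug-specific thresholds (2 MAD bands for alpha/beta, maximal
non-significant gamma for gamma).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._mahalanobis import mahalanobis_in_basis, pca_mahalanobis

__all__ = [
    "Decomposition",
    "DegenerateGeometryError",
    "NICloud",
    "EffectThresholds",
    "InteractionCall",
    "Edge",
    "decompose",
    "enumerate_interaction_classes",
    "build_ni_cloud",
    "interaction_significance",
    "derive_effect_thresholds",
    "classify",
    "NON_INTERACTION",
]

STATE_DECREASED = "decreased"
STATE_UNCHANGED = "unchanged"
STATE_INCREASED = "increased"
NON_INTERACTION = (STATE_UNCHANGED, STATE_UNCHANGED, False)


class DegenerateGeometryError(ValueError):
    """The two single vectors are (numerically) collinear.

    The in-plane solve is ill-posed; ``projection`` carries the 1-D
    projection coefficient of c onto a as a diagnostic.
    """

    def __init__(self, message: str, projection: float | None = None):
        super().__init__(message)
        self.projection = projection


@dataclass
class Decomposition:
    """Coefficients of c = alpha*a + beta*b + gamma*n_hat."""

    alpha: float
    beta: float
    gamma: float
    n_hat: np.ndarray
    reconstruction_error: float

    @property
    def in_plane(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


def decompose(a: np.ndarray, b: np.ndarray, c: np.ndarray, cond_max: float = 1e8) -> Decomposition:
    """Decompose a combination vector against its two single vectors.

    Solves the normal equations A p = h with A = [[a.a, a.b], [a.b, b.b]]
    and h = (a.c, b.c) for the in-plane coefficients, then takes the
    out-of-plane residual.  gamma is non-negative by convention; the unit
    direction n_hat is the zero vector when gamma = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("a, b, c must have the same dimension")
    aa, bb, ab = a @ a, b @ b, a @ b
    if aa == 0.0 or bb == 0.0:
        raise ValueError("single-perturbation vectors must be nonzero")
    gram = np.array([[aa, ab], [ab, bb]])
    if np.linalg.cond(gram) > cond_max:
        raise DegenerateGeometryError(
            "single-perturbation vectors are collinear; plane undefined",
            projection=float((a @ c) / aa),
        )
    alpha, beta = np.linalg.solve(gram, np.array([a @ c, b @ c]))
    residual = c - alpha * a - beta * b
    gamma = float(np.linalg.norm(residual))
    n_hat = residual / gamma if gamma > 0 else np.zeros_like(residual)
    recon = alpha * a + beta * b + gamma * n_hat
    return Decomposition(
        alpha=float(alpha),
        beta=float(beta),
        gamma=gamma,
        n_hat=n_hat,
        reconstruction_error=float(np.linalg.norm(c - recon)),
    )


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_SIGN_STATE = {-1: STATE_DECREASED, 0: STATE_UNCHANGED, 1: STATE_INCREASED}


def _category(state_a: str, state_b: str, emergent: bool) -> str:
    changed = (state_a != STATE_UNCHANGED) + (state_b != STATE_UNCHANGED)
    if changed == 0:
        return "undirected"
    if changed == 1:
        return "uni-directional"
    return "bi-directional"


def enumerate_interaction_classes() -> dict:
    """Enumerate the sign-pattern taxonomy of pairwise interactions.

    Returns the 27 subspaces of sign patterns of (alpha-1, beta-1, gamma)
    with their dimensionality, the histogram of subspace dimensions, and
    the 18 interaction classes left after merging the two signs of the
    emergent component, split into 2 undirected / 8 uni-directional / 8
    bi-directional categories.
    """
    subspaces = []
    for sa, sb, sg in itertools.product((-1, 0, 1), repeat=3):
        subspaces.append(
            {
                "signs": (sa, sb, sg),
                "dimension": int(sa != 0) + int(sb != 0) + int(sg != 0),
            }
        )
    dim_hist = {d: sum(1 for s in subspaces if s["dimension"] == d) for d in range(4)}

    classes = {}
    for s in subspaces:
        sa, sb, sg = s["signs"]
        key = (_SIGN_STATE[sa], _SIGN_STATE[sb], sg != 0)
        classes.setdefault(key, []).append(s["signs"])
    class_list = [
        {
            "state_a": k[0],
            "state_b": k[1],
            "emergent": k[2],
            "category": _category(*k),
            "merged_subspaces": v,
        }
        for k, v in sorted(classes.items())
    ]
    category_counts = {}
    for c in class_list:
        category_counts[c["category"]] = category_counts.get(c["category"], 0) + 1
    return {
        "subspaces": subspaces,
        "n_subspaces": len(subspaces),
        "dimension_histogram": dim_hist,
        "classes": class_list,
        "n_classes": len(class_list),
        "category_counts": category_counts,
    }


# ---------------------------------------------------------------------------
# non-interaction cloud and significance
# ---------------------------------------------------------------------------

@dataclass
class NICloud:
    """Expected non-interaction combination vectors for one drug pair.

    One point per (replicate of A, replicate of B, control well): the
    replicate-pair sum carries the replicate variability of the singles,
    the control-well perturbation carries the intra-plate well-to-well
    variation.
    """

    points: np.ndarray
    n_reps_a: int
    n_reps_b: int
    n_controls: int

    @property
    def mean(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def covariance(self) -> np.ndarray:
        return np.cov(self.points, rowvar=False)

    def __len__(self) -> int:
        return len(self.points)


def build_ni_cloud(
    reps_a: np.ndarray,
    reps_b: np.ndarray,
    control_wells: np.ndarray,
    control_reference: np.ndarray,
    mode: str = "multiplicative",
    eps: float = 1e-9,
) -> NICloud:
    """Build the non-interaction point cloud for one drug pair.

    ``control_wells`` are the raw control feature rows of the combination's
    plate and ``control_reference`` their per-feature median.  In
    ``multiplicative`` mode each replicate-pair sum is multiplied
    element-wise by the control well expressed as a ratio to the reference
    (ratios near 1); in ``additive`` mode the control's deviation from the
    reference is added instead.  Features whose reference is numerically
    zero get a neutral ratio of 1.
    """
    reps_a = np.atleast_2d(np.asarray(reps_a, dtype=float))
    reps_b = np.atleast_2d(np.asarray(reps_b, dtype=float))
    control_wells = np.atleast_2d(np.asarray(control_wells, dtype=float))
    control_reference = np.asarray(control_reference, dtype=float)
    if control_wells.shape[0] == 0:
        raise ValueError(
            "no control wells on the combination's plate; "
            "fall back to batch-level controls"
        )

    sums = reps_a[:, None, :] + reps_b[None, :, :]          # (na, nb, d)
    sums = sums.reshape(-1, reps_a.shape[1])                 # (na*nb, d)
    if mode == "multiplicative":
        safe_ref = np.where(np.abs(control_reference) < eps, 1.0, control_reference)
        ratios = control_wells / safe_ref
        ratios[:, np.abs(control_reference) < eps] = 1.0
        points = sums[:, None, :] * ratios[None, :, :]
    elif mode == "additive":
        deviations = control_wells - control_reference
        points = sums[:, None, :] + deviations[None, :, :]
    else:
        raise ValueError(f"unknown cloud mode {mode!r}")
    points = points.reshape(-1, reps_a.shape[1])
    return NICloud(
        points=points,
        n_reps_a=reps_a.shape[0],
        n_reps_b=reps_b.shape[0],
        n_controls=control_wells.shape[0],
    )


def interaction_significance(
    c_obs: np.ndarray,
    cloud: NICloud,
    variance_target: float = 0.90,
    cutoff: float = 3.0,
    ridge: float = 1e-8,
    basis: np.ndarray | None = None,
) -> tuple[float, bool, int]:
    """Mahalanobis distance D_I of the observed combination from the cloud.

    Noise reduction happens in a principal-component space explaining
    ``variance_target`` of the variance: by default that of the cloud
    itself; a screen-level ``basis`` (components fitted on all treatment
    vectors, shape (k, d)) may be supplied instead, so that the retained
    directions reflect where treatments vary rather than where this
    pair's cloud happens to spread.  The cloud's mean and covariance are
    estimated in the reduced space.  Returns (D_I, significant flag,
    number of components used).
    """
    if len(cloud) < 3:
        raise ValueError("non-interaction cloud too small for a covariance estimate")
    if basis is None:
        metric = pca_mahalanobis(cloud.points, variance_target, ridge)
    else:
        metric = mahalanobis_in_basis(cloud.points, basis, ridge)
    d_i = metric.distance(np.asarray(c_obs, dtype=float))
    return float(d_i), bool(d_i > cutoff), metric.n_components


# ---------------------------------------------------------------------------
# effect-size thresholds and classification
# ---------------------------------------------------------------------------

@dataclass
class EffectThresholds:
    """Per-drug effect-size gates derived from non-significant pairs.

    ``alpha_band``/``beta_band`` are (low, high) intervals outside which a
    coefficient counts as changed; ``t_gamma`` is the largest gamma seen
    among the drug's non-significant pairs.
    """

    alpha_band: tuple[float, float]
    beta_band: tuple[float, float]
    t_gamma: float
    n_pairs: int
    fallback: bool = False


def _mad(values: np.ndarray) -> float:
    med = np.median(values)
    return float(np.median(np.abs(values - med)))


def _band(values: np.ndarray, k: float) -> tuple[float, float]:
    med = float(np.median(values))
    mad = _mad(values)
    return (med - k * mad, med + k * mad)


def derive_effect_thresholds(
    nonsignificant: Mapping[object, Sequence[tuple[float, float, float]]],
    mad_k: float = 2.0,
    min_pairs: int = 5,
) -> dict:
    """Drug-specific effect-size thresholds from non-significant pairs.

    ``nonsignificant`` maps each drug to the (alpha, beta, gamma) triples
    of its non-significant pairs, oriented so that the first coefficient
    is the drug's own scaling.  The alpha band is median +/- ``mad_k`` MAD
    of those own-scaling values, the gamma threshold is their maximal
    gamma.  Drugs with fewer than ``min_pairs`` entries fall back to
    global thresholds pooled over all drugs, flagged as such.
    """
    pooled_own, pooled_other, pooled_gamma = [], [], []
    for triples in nonsignificant.values():
        for own, other, g in triples:
            pooled_own.append(own)
            pooled_other.append(other)
            pooled_gamma.append(g)
    if not pooled_own:
        raise ValueError("no non-significant pairs available for thresholds")
    global_thr = EffectThresholds(
        alpha_band=_band(np.array(pooled_own), mad_k),
        beta_band=_band(np.array(pooled_other), mad_k),
        t_gamma=float(np.max(pooled_gamma)),
        n_pairs=len(pooled_own),
        fallback=True,
    )

    out = {}
    for drug, triples in nonsignificant.items():
        if len(triples) < min_pairs:
            out[drug] = global_thr
            continue
        own = np.array([t[0] for t in triples])
        other = np.array([t[1] for t in triples])
        gammas = np.array([t[2] for t in triples])
        out[drug] = EffectThresholds(
            alpha_band=_band(own, mad_k),
            beta_band=_band(other, mad_k),
            t_gamma=float(np.max(gammas)),
            n_pairs=len(triples),
        )
    out["__global__"] = global_thr
    return out


@dataclass
class Edge:
    source: object
    target: object
    kind: str            # "positive" | "negative" | "emergent"
    directed: bool


@dataclass
class InteractionCall:
    """Final interaction call for one drug pair."""

    pair: tuple
    alpha: float
    beta: float
    gamma: float
    d_i: float
    significant: bool
    state_a: str
    state_b: str
    emergent: bool
    category: str
    edges: list = field(default_factory=list)

    @property
    def interaction_class(self) -> tuple[str, str, bool]:
        return (self.state_a, self.state_b, self.emergent)

    @property
    def is_interaction(self) -> bool:
        return self.interaction_class != NON_INTERACTION


def _coefficient_state(value: float, band: tuple[float, float]) -> str:
    lo, hi = band
    if value < lo:
        return STATE_DECREASED
    if value > hi:
        return STATE_INCREASED
    return STATE_UNCHANGED


def classify(
    pair: tuple,
    dec: Decomposition,
    d_i: float,
    thresholds_a: EffectThresholds,
    thresholds_b: EffectThresholds,
    di_cutoff: float = 3.0,
) -> InteractionCall:
    """Turn a decomposition plus significance into an interaction call.

    A pair is an interaction only if D_I exceeds the cutoff AND at least
    one coefficient clears its effect-size gate; a significant pair with
    all coefficients inside their bands is conservatively called
    non-interaction.  alpha is gated by drug A's own band, beta by drug
    B's, and gamma by the larger of the two drugs' gamma thresholds (the
    emergent component is shared).

    Edges: a changed alpha means B modulated A's effect (directed edge
    B -> A, positive when increased); symmetrically for beta; an emergent
    component adds an undirected A -- B edge.
    """
    a_name, b_name = pair
    significant = d_i > di_cutoff
    if not significant:
        return InteractionCall(
            pair=pair, alpha=dec.alpha, beta=dec.beta, gamma=dec.gamma,
            d_i=d_i, significant=False,
            state_a=STATE_UNCHANGED, state_b=STATE_UNCHANGED, emergent=False,
            category="undirected",
        )
    state_a = _coefficient_state(dec.alpha, thresholds_a.alpha_band)
    state_b = _coefficient_state(dec.beta, thresholds_b.beta_band)
    t_gamma = max(thresholds_a.t_gamma, thresholds_b.t_gamma)
    emergent = dec.gamma > t_gamma

    edges = []
    if state_a == STATE_INCREASED:
        edges.append(Edge(b_name, a_name, "positive", True))
    elif state_a == STATE_DECREASED:
        edges.append(Edge(b_name, a_name, "negative", True))
    if state_b == STATE_INCREASED:
        edges.append(Edge(a_name, b_name, "positive", True))
    elif state_b == STATE_DECREASED:
        edges.append(Edge(a_name, b_name, "negative", True))
    if emergent:
        edges.append(Edge(a_name, b_name, "emergent", False))

    return InteractionCall(
        pair=pair, alpha=dec.alpha, beta=dec.beta, gamma=dec.gamma,
        d_i=d_i, significant=True,
        state_a=state_a, state_b=state_b, emergent=emergent,
        category=_category(state_a, state_b, emergent),
        edges=edges,
    )
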