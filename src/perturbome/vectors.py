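"""Perturbation vectors in the filtered morphological space.

A perturbation is represented by a displacement vector pointing from the
unperturbed (DMSO-treated) centroid to the perturbed state.  Single-drug
treatments have one vector per replicate well and a mean vector;
combination treatments are measured once.  The strength of a perturbation
is the Mahalanobis distance D_P of its vector from the control-well
distribution, computed after projecting onto the principal components of
the controls that explain a target fraction (default 90%) of their
variance; D_P generalises the z-score to many dimensions and a cutoff of
D_P > 7 (in at least one batch) separates strong from weak perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._mahalanobis import pca_mahalanobis
from .normalize import ROLE_COMBINATION, ROLE_CONTROL, ROLE_SINGLE, WellFeatureTable

__all__ = [
    "PerturbationVector",
    "StrengthResult",
    "VectorSet",
    "compute_vectors",
    "perturbation_strength",
    "cosine_similarity",
    "norm_filter",
]


@dataclass
class PerturbationVector:
    """Displacement of one treatment from the control centroid.

    ``replicates`` holds one row per replicate well; ``mean`` is their
    arithmetic mean (equal to the single row for combinations).
    """

    treatment: object
    mean: np.ndarray
    replicates: np.ndarray
    batch: object                      # single batch id, or list when pooled
    plates: list = field(default_factory=list)
    replicates_by_batch: dict = field(default_factory=dict)

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.mean))

    @property
    def n_replicates(self) -> int:
        return int(self.replicates.shape[0])


@dataclass
class StrengthResult:
    treatment: object
    d_p: float                     # maximum over batches
    d_p_by_batch: dict
    n_components: int
    explained_variance: float
    strong: bool


@dataclass
class VectorSet:
    """All vectors of a screen plus the control context needed downstream.

    ``controls`` maps batch -> (n_wells, d) array of control displacement
    vectors (control wells minus the batch control centroid).
    ``plate_controls`` maps plate -> the raw control-well feature rows of
    that plate, and ``plate_control_median`` their per-feature median;
    both are needed to build non-interaction clouds that carry the
    intra-plate variation.
    """

    singles: dict
    combinations: dict
    controls: dict
    plate_controls: dict
    plate_control_median: dict
    features: list[str]


def compute_vectors(
    wells: WellFeatureTable,
    features: list[str] | None = None,
    valid_wells: pd.Series | None = None,
) -> VectorSet:
    """Build displacement vectors for every treatment.

    Each replicate vector is the well's feature row minus the centroid of
    the DMSO control wells of the same batch.  Treatments without any
    valid well are omitted (their ids are recoverable from the metadata).
    """
    features = features or list(wells.values.columns)
    values = wells.values[features]
    meta = wells.meta
    if valid_wells is not None:
        keep = valid_wells.reindex(meta.index).fillna(False).astype(bool)
    else:
        keep = pd.Series(True, index=meta.index)

    centroids = {}
    controls: dict = {}
    for batch, bmeta in meta[meta["role"] == ROLE_CONTROL].groupby("batch"):
        idx = bmeta.index[keep.loc[bmeta.index]]
        if len(idx) == 0:
            raise ValueError(f"batch {batch!r} has no valid control wells")
        block = values.loc[idx].to_numpy()
        centroids[batch] = block.mean(axis=0)
        controls[batch] = block - centroids[batch]

    plate_controls = {}
    plate_control_median = {}
    for plate, pmeta in meta[meta["role"] == ROLE_CONTROL].groupby(level="plate"):
        idx = pmeta.index[keep.loc[pmeta.index]]
        block = values.loc[idx].to_numpy()
        plate_controls[plate] = block
        plate_control_median[plate] = np.median(block, axis=0)

    singles = {}
    for drug, dmeta_all in meta[meta["role"] == ROLE_SINGLE].groupby("drug_a"):
        by_batch = {}
        plates: list = []
        for batch, dmeta in dmeta_all.groupby("batch"):
            idx = dmeta.index[keep.loc[dmeta.index]]
            if len(idx) == 0:
                continue
            by_batch[batch] = values.loc[idx].to_numpy() - centroids[batch]
            plates.extend(idx.get_level_values("plate"))
        if not by_batch:
            continue
        reps = np.vstack(list(by_batch.values()))
        batches = sorted(by_batch)
        singles[drug] = PerturbationVector(
            treatment=drug,
            mean=reps.mean(axis=0),
            replicates=reps,
            batch=batches[0] if len(batches) == 1 else batches,
            plates=plates,
            replicates_by_batch=by_batch,
        )

    combinations = {}
    for (batch, a, b), cmeta in meta[meta["role"] == ROLE_COMBINATION].groupby(
        ["batch", "drug_a", "drug_b"]
    ):
        idx = cmeta.index[keep.loc[cmeta.index]]
        if len(idx) == 0:
            continue
        reps = values.loc[idx].to_numpy() - centroids[batch]
        combinations[(a, b)] = PerturbationVector(
            treatment=(a, b),
            mean=reps.mean(axis=0),
            replicates=reps,
            batch=batch,
            plates=list(idx.get_level_values("plate")),
        )
    return VectorSet(
        singles=singles,
        combinations=combinations,
        controls=controls,
        plate_controls=plate_controls,
        plate_control_median=plate_control_median,
        features=features,
    )


def perturbation_strength(
    vectors: Mapping[object, PerturbationVector],
    controls: Mapping[object, np.ndarray],
    variance_target: float = 0.90,
    cutoff: float = 7.0,
    ridge: float = 1e-8,
) -> dict:
    """Mahalanobis strength D_P of each perturbation against control variation.

    The principal-component basis and covariance are fitted on the control
    displacement vectors of each batch; a perturbation is strong when its
    (replicate-mean) vector exceeds ``cutoff`` in at least one batch.
    """
    metrics = {
        batch: pca_mahalanobis(np.asarray(block), variance_target, ridge)
        for batch, block in controls.items()
    }
    out = {}
    for key, vec in vectors.items():
        by_batch = {}
        batches = vec.batch if isinstance(vec.batch, (list, tuple, set)) else [vec.batch]
        for batch in batches:
            # replicate-mean vector within the batch being tested
            reps = vec.replicates_by_batch.get(batch)
            x = reps.mean(axis=0) if reps is not None else vec.mean
            by_batch[batch] = metrics[batch].distance(x)
        best_batch = max(by_batch, key=by_batch.get)
        d_p = by_batch[best_batch]
        out[key] = StrengthResult(
            treatment=key,
            d_p=float(d_p),
            d_p_by_batch=by_batch,
            n_components=metrics[best_batch].n_components,
            explained_variance=metrics[best_batch].explained_variance,
            strong=bool(d_p > cutoff),
        )
    return out


def cosine_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    Only the orientation matters: two magnitudes of the same phenotype
    score 1.  A zero vector has no orientation; NaN is returned as a
    flagged missing value.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("vectors must have equal dimension")
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return float("nan")
    return float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))


def norm_filter(
    vectors: Mapping[object, PerturbationVector],
    control_vectors: np.ndarray,
    k_sd: float = 2.0,
) -> tuple[dict, float]:
    """Keep vectors whose length clears the DMSO vector-norm background.

    The retention threshold is mean + ``k_sd`` standard deviations of the
    control-well vector norms; vectors at or below it are treated as
    unperturbed-like and removed.  Returns the retained mapping and the
    threshold used.
    """
    norms = np.linalg.norm(np.asarray(control_vectors, dtype=float), axis=1)
    threshold = float(norms.mean() + k_sd * norms.std(ddof=0))
    kept = {k: v for k, v in vectors.items() if v.norm > threshold}
    return kept, threshold
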