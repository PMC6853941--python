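"""Well aggregation, plate normalisation and screen-level filtering.

This module turns raw per-cell morphological feature tables into a clean,
normalised well x feature matrix and decides which features and which drug
perturbations are reliable enough to enter the vector-based interaction
analysis.  The processing chain is

1. :func:`aggregate_wells` -- median of every feature over the cells of a
   well (robust against outlier cells and segmentation errors),
2. :func:`polish` -- Tukey's median polish per plate and feature, removing
   additive row/column artefacts such as edge evaporation,
3. :func:`scale_unit_interval` -- percentile-clipped min--max scaling of
   every feature to [0, 1] within a batch,
4. :func:`filter_features` -- four-stage cascade keeping only robust,
   reproducible, informative and non-redundant features,
5. :func:`filter_perturbations` -- well- and drug-level validity calls
   (cell-count floor, replicate floor, temporal stability of activity).

The well metadata table is the backbone of all later stages.  Required
columns are: ``row``, ``col`` (plate grid position), ``batch``, ``role``
(one of ``control``/``single``/``combination``), ``drug_a``, ``drug_b``
(empty for controls; ``drug_b`` empty for singles), ``replicate``,
``time_order`` (temporal plating order of replicates), ``cell_count``.
Tables are indexed by (plate, well).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NormalizeConfig",
    "WellFeatureTable",
    "FeatureSelection",
    "PerturbationValidity",
    "MedianPolishResult",
    "aggregate_wells",
    "median_polish",
    "polish_plate",
    "polish",
    "scale_unit_interval",
    "filter_features",
    "filter_perturbations",
]

META_COLUMNS = (
    "row", "col", "batch", "role", "drug_a", "drug_b",
    "replicate", "time_order", "cell_count",
)

ROLE_CONTROL = "control"
ROLE_SINGLE = "single"
ROLE_COMBINATION = "combination"


@dataclass
class NormalizeConfig:
    """All preprocessing thresholds in one place.

    Defaults follow the screening protocol: coefficient-of-variation
    ceiling 0.2 for control wells, replicate-correlation floor 0.2,
    Bonferroni-corrected significance level 0.05, redundancy correlation
    ceiling 0.8, at least 30 cells per well and 3 valid wells per drug,
    stability slope ceiling 0.05 together with a 30% relative cell-count
    difference, and percentile clipping at the 0.5th/99.5th percentiles.
    """

    cv_max: float = 0.2
    replicate_corr_min: float = 0.2
    alpha: float = 0.05
    redundancy_rho: float = 0.8
    min_cells: int = 30
    min_wells: int = 3
    stability_slope: float = 0.05
    stability_diff: float = 0.30
    clip_lower_pct: float = 0.5
    clip_upper_pct: float = 99.5

    @classmethod
    def from_json(cls, path: str) -> "NormalizeConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class WellFeatureTable:
    """Well x feature matrix plus per-well metadata.

    ``values`` and ``meta`` share a (plate, well) MultiIndex.  Provenance
    flags record which normalisation steps have been applied.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    aggregated: bool = True
    polished: bool = False
    scaled: bool = False
    excluded_wells: list = field(default_factory=list)
    flagged_features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata is missing required columns: {missing}")
        if not self.values.index.isin(self.meta.index).all():
            raise ValueError("every well in the value table must appear in the metadata")
        self.meta = self.meta.loc[self.values.index]

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def subset_features(self, features: Iterable[str]) -> "WellFeatureTable":
        return WellFeatureTable(
            values=self.values[list(features)].copy(),
            meta=self.meta,
            aggregated=self.aggregated,
            polished=self.polished,
            scaled=self.scaled,
            excluded_wells=list(self.excluded_wells),
            flagged_features=list(self.flagged_features),
        )

    def control_mask(self) -> pd.Series:
        return self.meta["role"] == ROLE_CONTROL


@dataclass
class FeatureSelection:
    """Outcome of the four-stage feature filter.

    ``diagnostics`` has one row per input feature with its intra-/inter-
    plate CV, mean replicate correlation, maximal |z| effect size and the
    stage at which it was removed (or ``kept``).
    """

    retained: list[str]
    diagnostics: pd.DataFrame

    def removal_stage(self, feature: str) -> str:
        return str(self.diagnostics.loc[feature, "removed_at"])


@dataclass
class PerturbationValidity:
    """Per-drug validity flags plus per-well cell-count flags."""

    drugs: pd.DataFrame        # index drug; pass/fail per criterion
    wells: pd.DataFrame        # index (plate, well); valid flag and reason

    @property
    def valid_drugs(self) -> list[str]:
        return list(self.drugs.index[self.drugs["valid"]])


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_wells(cells: pd.DataFrame, meta: pd.DataFrame) -> WellFeatureTable:
    """Collapse a per-cell table to per-well feature medians.

    ``cells`` is a wide table with ``plate`` and ``well`` columns (and
    optionally ``cell``) followed by numeric feature columns.  Wells listed
    in ``meta`` but absent from ``cells`` are excluded with a recorded
    reason rather than raising.
    """
    id_cols = [c for c in ("plate", "well", "cell") if c in cells.columns]
    if "plate" not in id_cols or "well" not in id_cols:
        raise ValueError("cell table must have 'plate' and 'well' columns")
    feature_cols = [c for c in cells.columns if c not in id_cols]
    if not feature_cols:
        raise ValueError("cell table contains no feature columns")
    values = np.asarray(cells[feature_cols], dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("cell feature values must be finite")

    medians = cells.groupby(["plate", "well"], sort=True)[feature_cols].median()
    if not isinstance(meta.index, pd.MultiIndex):
        meta = meta.set_index(["plate", "well"])
    excluded = [
        (plate, well, "no cells measured")
        for plate, well in meta.index.difference(medians.index)
    ]
    orphans = medians.index.difference(meta.index)
    if len(orphans):
        raise ValueError(f"wells missing from the plate map: {list(orphans)[:5]}")
    medians = medians.loc[medians.index.intersection(meta.index)]
    return WellFeatureTable(
        values=medians,
        meta=meta.loc[medians.index],
        excluded_wells=excluded,
    )


# ---------------------------------------------------------------------------
# Tukey median polish
# ---------------------------------------------------------------------------

@dataclass
class MedianPolishResult:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    n_iter: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )


def median_polish(
    table: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> MedianPolishResult:
    """Tukey's median polish of a two-way table.

    Iteratively sweeps out row and column medians until the additive model
    ``value = overall + row + col + residual`` stabilises.  Sweeps start
    with rows; ties in medians use the midpoint convention of
    :func:`numpy.median`.  NaN entries (absent wells) are ignored when
    taking medians and keep NaN residuals.
    """
    x = np.array(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("median polish expects a 2-D table")
    n_rows, n_cols = x.shape
    overall = 0.0
    row = np.zeros(n_rows)
    col = np.zeros(n_cols)
    resid = x.copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        max_change = 0.0
        if n_rows > 1 or n_cols == 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rmed = np.nanmedian(resid, axis=1)
            rmed = np.where(np.isnan(rmed), 0.0, rmed)
            resid -= rmed[:, None]
            row += rmed
            max_change = max(max_change, float(np.max(np.abs(rmed), initial=0.0)))
            delta = float(np.median(col))
            col -= delta
            overall += delta
        if n_cols > 1 or n_rows == 1:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cmed = np.nanmedian(resid, axis=0)
            cmed = np.where(np.isnan(cmed), 0.0, cmed)
            resid -= cmed[None, :]
            col += cmed
            max_change = max(max_change, float(np.max(np.abs(cmed), initial=0.0)))
            delta = float(np.median(row))
            row -= delta
            overall += delta
        if max_change < tol:
            converged = True
            break
    return MedianPolishResult(overall, row, col, resid, n_iter, converged)


def polish_plate(
    wells: WellFeatureTable,
    feature: str,
    plate: object | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[pd.Series, pd.Series, pd.Series, float]:
    """Median-polish one feature on one plate.

    Returns the polished values (overall median + residual; row/column
    effects removed), the row effects, the column effects and the overall
    median.  Plates with a single row (or column) fall back to a
    column-only (row-only) polish with a warning.
    """
    meta = wells.meta
    if plate is None:
        plates = meta.index.get_level_values("plate").unique()
        if len(plates) != 1:
            raise ValueError("multiple plates present; pass `plate` explicitly")
        plate = plates[0]
    on_plate = meta.index.get_level_values("plate") == plate
    sub_meta = meta[on_plate]
    sub_vals = wells.values.loc[sub_meta.index, feature]

    rows = np.sort(sub_meta["row"].unique())
    cols = np.sort(sub_meta["col"].unique())
    if len(rows) == 1 or len(cols) == 1:
        warnings.warn(
            f"plate {plate!r} has a single {'row' if len(rows) == 1 else 'column'}; "
            "polishing the other dimension only",
            stacklevel=2,
        )
    r_index = {r: i for i, r in enumerate(rows)}
    c_index = {c: i for i, c in enumerate(cols)}
    grid = np.full((len(rows), len(cols)), np.nan)
    for (idx, m), v in zip(sub_meta.iterrows(), sub_vals):
        grid[r_index[m["row"]], c_index[m["col"]]] = v
    res = median_polish(grid, tol=tol, max_iter=max_iter)

    polished = pd.Series(
        [
            res.overall + res.residuals[r_index[m["row"]], c_index[m["col"]]]
            for _, m in sub_meta.iterrows()
        ],
        index=sub_meta.index,
        name=feature,
    )
    row_eff = pd.Series(res.row_effects, index=rows, name="row_effect")
    col_eff = pd.Series(res.col_effects, index=cols, name="col_effect")
    return polished, row_eff, col_eff, res.overall


def polish(wells: WellFeatureTable, tol: float = 1e-6, max_iter: int = 100) -> WellFeatureTable:
    """Apply median polish to every feature on every plate."""
    out = wells.values.copy()
    plates = wells.meta.index.get_level_values("plate").unique()
    for plate in plates:
        for feature in wells.features:
            polished, _, _, _ = polish_plate(wells, feature, plate=plate, tol=tol, max_iter=max_iter)
            out.loc[polished.index, feature] = polished
    return WellFeatureTable(
        values=out,
        meta=wells.meta,
        aggregated=wells.aggregated,
        polished=True,
        scaled=wells.scaled,
        excluded_wells=list(wells.excluded_wells),
        flagged_features=list(wells.flagged_features),
    )


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

def scale_unit_interval(
    wells: WellFeatureTable,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
) -> WellFeatureTable:
    """Clip each feature at batch-level percentiles and rescale to [0, 1].

    Values outside the (``lower_pct``, ``upper_pct``) percentiles are
    treated as outliers: they are clipped to the bounds, which map exactly
    to 0 and 1.  A zero-variance feature (upper bound equal to lower bound)
    maps to 0.5 everywhere and is flagged.
    """
    out = wells.values.copy()
    flagged = list(wells.flagged_features)
    for batch, batch_meta in wells.meta.groupby("batch"):
        idx = batch_meta.index
        block = out.loc[idx]
        lo = np.percentile(block, lower_pct, axis=0)
        hi = np.percentile(block, upper_pct, axis=0)
        span = hi - lo
        degenerate = span <= 0
        scaled = np.clip(block.to_numpy(), lo, hi)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = (scaled - lo) / span
        scaled[:, degenerate] = 0.5
        out.loc[idx] = scaled
        for f in block.columns[degenerate]:
            flagged.append((f, f"zero variance in batch {batch}"))
    return WellFeatureTable(
        values=out,
        meta=wells.meta,
        aggregated=wells.aggregated,
        polished=wells.polished,
        scaled=True,
        excluded_wells=list(wells.excluded_wells),
        flagged_features=flagged,
    )


# ---------------------------------------------------------------------------
# feature filtering
# ---------------------------------------------------------------------------

def _control_cvs(values: pd.DataFrame, meta: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Intra- and inter-plate coefficients of variation over control wells.

    Intra-plate CV is the per-plate sd/|mean| over control wells, averaged
    over plates.  Inter-plate CV is the sd/|mean| of the per-plate control
    means.  Requires at least 2 control wells on every plate.
    """
    ctrl = meta[meta["role"] == ROLE_CONTROL]
    if ctrl.empty:
        raise ValueError("no control wells in batch; CV undefined")
    per_plate_cv = []
    per_plate_mean = []
    for plate, plate_meta in ctrl.groupby(level="plate"):
        if len(plate_meta) < 2:
            raise ValueError(
                f"plate {plate!r} has fewer than 2 control wells; CV undefined"
            )
        block = values.loc[plate_meta.index]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        per_plate_cv.append(sd / mean.abs())
        per_plate_mean.append(mean)
    intra = pd.concat(per_plate_cv, axis=1).mean(axis=1)
    means = pd.concat(per_plate_mean, axis=1)
    if means.shape[1] < 2:
        inter = pd.Series(0.0, index=values.columns)
    else:
        inter = means.std(axis=1, ddof=1) / means.mean(axis=1).abs()
    return intra, inter


def _replicate_correlations(values: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Mean between-replicate Pearson correlation per feature.

    For each feature, single-drug wells are arranged into a drug x
    replicate matrix; the correlation is taken across drugs between every
    pair of replicate columns and averaged.  With fewer than 2 replicates
    (or 3 drugs) the correlation is undefined and reported as NaN.
    """
    singles = meta[meta["role"] == ROLE_SINGLE]
    out = {}
    for feature in values.columns:
        mat = (
            values.loc[singles.index, feature]
            .groupby([singles["drug_a"], singles["replicate"]])
            .mean()
            .unstack("replicate")
        )
        if mat.shape[1] < 2 or mat.shape[0] < 3:
            out[feature] = np.nan
            continue
        corrs = []
        cols = list(mat.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                pair = mat[[cols[i], cols[j]]].dropna()
                if len(pair) < 3:
                    continue
                with np.errstate(invalid="ignore"):
                    r = np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1]
                if np.isfinite(r):
                    corrs.append(r)
        out[feature] = float(np.mean(corrs)) if corrs else np.nan
    return pd.Series(out)


def _effect_z_scores(values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """z-score of each perturbation's mean shift, per feature.

    The shift of the treatment mean from the control mean is expressed in
    units of the control standard deviation within the batch.  Rows are
    perturbations (drug for singles, "A+B" for combinations), columns are
    features.
    """
    ctrl_idx = meta.index[meta["role"] == ROLE_CONTROL]
    mu = values.loc[ctrl_idx].mean(axis=0)
    sd = values.loc[ctrl_idx].std(axis=0, ddof=1)
    sd = sd.replace(0.0, np.nan)
    treated = meta[meta["role"].isin([ROLE_SINGLE, ROLE_COMBINATION])]
    labels = treated.apply(
        lambda m: m["drug_a"] if m["role"] == ROLE_SINGLE else f"{m['drug_a']}+{m['drug_b']}",
        axis=1,
    )
    grouped = values.loc[treated.index].groupby(labels).mean()
    return (grouped - mu) / sd


def filter_features(
    wells: WellFeatureTable,
    config: NormalizeConfig | None = None,
) -> FeatureSelection:
    """Four-stage feature filter cascade.

    Stages (applied in order, each to the survivors of the previous one):

    i.   drop features whose intra- or inter-plate control CV is >= ``cv_max``;
    ii.  drop features whose mean between-replicate correlation is below
         ``replicate_corr_min``;
    iii. drop features for which no perturbation reaches Bonferroni-corrected
         significance (two-sided normal p from the control z-score);
    iv.  iteratively drop the lower-effect member of the most-correlated
         feature pair while any retained pair exceeds ``redundancy_rho``.

    Stages i--iii run separately per batch and a feature must pass in every
    batch; stage iv runs once on the pooled wells.  Every removal records
    its stage.
    """
    config = config or NormalizeConfig()
    features = list(wells.values.columns)
    diag = pd.DataFrame(
        index=pd.Index(features, name="feature"),
        data={
            "intra_plate_cv": np.nan,
            "inter_plate_cv": np.nan,
            "replicate_corr": np.nan,
            "max_abs_z": np.nan,
            "removed_at": "kept",
        },
    )

    surviving = set(features)
    max_abs_z = pd.Series(0.0, index=features)
    batches = wells.meta["batch"].unique()
    for batch in batches:
        idx = wells.meta.index[wells.meta["batch"] == batch]
        values = wells.values.loc[idx]
        meta = wells.meta.loc[idx]

        # (i) control-well coefficient of variation
        intra, inter = _control_cvs(values, meta)
        diag["intra_plate_cv"] = diag["intra_plate_cv"].combine(intra, lambda a, b: np.nanmax([a, b]))
        diag["inter_plate_cv"] = diag["inter_plate_cv"].combine(inter, lambda a, b: np.nanmax([a, b]))
        noisy = set(intra.index[(intra >= config.cv_max) | (inter >= config.cv_max)])
        for f in sorted(noisy & surviving):
            diag.loc[f, "removed_at"] = "i:control_cv"
        surviving -= noisy

        # (ii) replicate reproducibility
        stage2_in = sorted(surviving)
        corr = _replicate_correlations(values[stage2_in], meta)
        diag.loc[stage2_in, "replicate_corr"] = np.fmin(
            diag.loc[stage2_in, "replicate_corr"], corr
        ).fillna(corr)
        weak = set(corr.index[corr < config.replicate_corr_min])
        for f in sorted(weak & surviving):
            diag.loc[f, "removed_at"] = "ii:replicate_corr"
        surviving -= weak

        # (iii) effect significance (Bonferroni over all feature x perturbation tests)
        stage3_in = sorted(surviving)
        if stage3_in:
            z = _effect_z_scores(values[stage3_in], meta)
            n_tests = int(np.isfinite(z.to_numpy()).sum())
            p = 2.0 * stats.norm.sf(np.abs(z))
            p_adj = np.minimum(p * max(n_tests, 1), 1.0)
            significant = (pd.DataFrame(p_adj, index=z.index, columns=z.columns) < config.alpha).any(axis=0)
            feat_max_z = z.abs().max(axis=0)
            max_abs_z.loc[stage3_in] = np.fmax(max_abs_z.loc[stage3_in], feat_max_z.fillna(0.0))
            inert = set(significant.index[~significant])
            for f in sorted(inert & surviving):
                diag.loc[f, "removed_at"] = "iii:no_effect"
            surviving -= inert

    diag["max_abs_z"] = max_abs_z

    # (iv) redundancy pruning on the pooled table
    retained = sorted(surviving)
    if len(retained) > 1:
        corr = wells.values[retained].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        names = list(retained)
        alive = np.ones(len(names), dtype=bool)
        while True:
            masked = np.where(np.outer(alive, alive), corr, 0.0)
            peak = masked.max()
            if peak <= config.redundancy_rho:
                break
            ii, jj = np.argwhere(masked == peak)[0]
            a, b = sorted((names[ii], names[jj]))  # lexicographic tie-break
            za, zb = max_abs_z[a], max_abs_z[b]
            drop = a if (za < zb or (za == zb and a > b)) else b
            alive[names.index(drop)] = False
            diag.loc[drop, "removed_at"] = "iv:redundant"
        retained = [n for n, keep in zip(names, alive) if keep]

    return FeatureSelection(retained=retained, diagnostics=diag)


# ---------------------------------------------------------------------------
# perturbation filtering
# ---------------------------------------------------------------------------

def filter_perturbations(
    wells: WellFeatureTable,
    config: NormalizeConfig | None = None,
) -> PerturbationValidity:
    """Flag invalid wells and unstable or under-replicated drugs.

    A well is invalid below ``min_cells`` cells.  A single-drug
    perturbation is invalid with fewer than ``min_wells`` valid wells, or
    when its activity decays over the screen: the per-well cell count,
    normalised by the same-plate control median count, is regressed on the
    temporal replicate order, and the drug fails when the fitted slope
    exceeds ``stability_slope`` AND the relative difference between its
    largest and smallest well cell count is at least ``stability_diff``.
    Drugs with a single time point are marked "not assessed" for stability.
    """
    config = config or NormalizeConfig()
    meta = wells.meta

    well_valid = meta["cell_count"] >= config.min_cells
    well_report = pd.DataFrame(
        {
            "valid": well_valid,
            "reason": np.where(well_valid, "", f"fewer than {config.min_cells} cells"),
        },
        index=meta.index,
    )

    # same-plate DMSO median cell count for normalisation
    ctrl = meta[meta["role"] == ROLE_CONTROL]
    plate_ctrl_median = ctrl.groupby(level="plate")["cell_count"].median()

    rows = []
    singles = meta[meta["role"] == ROLE_SINGLE]
    for drug, dmeta in singles.groupby("drug_a"):
        valid = well_valid.loc[dmeta.index]
        n_valid = int(valid.sum())
        enough_wells = n_valid >= config.min_wells

        counts = dmeta["cell_count"].astype(float)
        plates = dmeta.index.get_level_values("plate")
        norm_counts = counts.to_numpy() / plate_ctrl_median.reindex(plates).to_numpy()
        order = dmeta["time_order"].astype(float).to_numpy()

        if len(np.unique(order)) < 2:
            slope, intercept = np.nan, np.nan
            stability_assessed = False
            stable = True
        else:
            stability_assessed = True
            slope, intercept = np.polyfit(order, norm_counts, 1)
            cmax, cmin = counts.max(), counts.min()
            rel_diff = (cmax - cmin) / cmax if cmax > 0 else 0.0
            stable = not (slope > config.stability_slope and rel_diff >= config.stability_diff)
        cmax, cmin = counts.max(), counts.min()
        rel_diff = float((cmax - cmin) / cmax) if cmax > 0 else 0.0

        rows.append(
            {
                "drug": drug,
                "n_valid_wells": n_valid,
                "enough_wells": enough_wells,
                "slope": slope,
                "intercept": intercept,
                "rel_count_diff": rel_diff,
                "stability_assessed": stability_assessed,
                "stable": stable,
                "valid": bool(enough_wells and stable),
            }
        )
    drugs = pd.DataFrame(rows).set_index("drug") if rows else pd.DataFrame(
        columns=["n_valid_wells", "enough_wells", "slope", "intercept",
                 "rel_count_diff", "stability_assessed", "stable", "valid"]
    )
    return PerturbationValidity(drugs=drugs, wells=well_report)
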