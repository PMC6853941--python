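"""Well aggregation, median polish, scaling and the filter cascades."""

import numpy as np
import pandas as pd
import pytest

from perturbome.normalize import (
    NormalizeConfig,
    aggregate_wells,
    filter_features,
    filter_perturbations,
    median_polish,
    polish,
    polish_plate,
    scale_unit_interval,
)

from conftest import make_meta, make_wells


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregateWells:
    def _cells(self, values_by_well):
        rows = []
        for well, values in values_by_well.items():
            for i, v in enumerate(values):
                rows.append({"plate": "P0", "well": well, "cell": i, "f0": v})
        return pd.DataFrame(rows)

    def test_median_of_cells(self):
        cells = self._cells({"A1": [1.0, 2.0, 9.0]})
        meta = make_meta([{"plate": "P0", "well": "A1"}])
        wells = aggregate_wells(cells, meta)
        assert wells.values.loc[("P0", "A1"), "f0"] == 2.0

    def test_single_cell_passes_verbatim(self):
        cells = self._cells({"A1": [7.25]})
        meta = make_meta([{"plate": "P0", "well": "A1"}])
        wells = aggregate_wells(cells, meta)
        assert wells.values.loc[("P0", "A1"), "f0"] == 7.25

    def test_matches_sort_and_pick_middle_oracle(self, rng):
        values = rng.normal(size=50)
        cells = self._cells({"A1": values})
        meta = make_meta([{"plate": "P0", "well": "A1"}])
        wells = aggregate_wells(cells, meta)
        s = np.sort(values)
        oracle = 0.5 * (s[24] + s[25])
        assert wells.values.loc[("P0", "A1"), "f0"] == pytest.approx(oracle)

    def test_missing_well_excluded_with_reason(self):
        cells = self._cells({"A1": [1.0]})
        meta = make_meta([{"plate": "P0", "well": "A1"},
                          {"plate": "P0", "well": "A2"}])
        wells = aggregate_wells(cells, meta)
        assert ("P0", "A2", "no cells measured") in wells.excluded_wells
        assert ("P0", "A2") not in wells.values.index


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

class TestMedianPolish:
    def test_constant_table(self):
        res = median_polish(np.full((4, 6), 0.4))
        assert res.overall == pytest.approx(0.4)
        assert np.allclose(res.row_effects, 0)
        assert np.allclose(res.col_effects, 0)
        assert np.allclose(res.residuals, 0)

    def test_two_by_two_hand_oracle(self):
        # [[1,2],[3,4]]: overall 2.5, rows (-1, 1), cols (-0.5, 0.5)
        res = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert res.overall == pytest.approx(2.5)
        assert np.allclose(res.row_effects, [-1.0, 1.0])
        assert np.allclose(res.col_effects, [-0.5, 0.5])
        assert np.allclose(res.residuals, 0)

    def test_planted_additive_recovery_16x24(self, rng):
        rows = rng.normal(0, 0.05, 16)
        cols = rng.normal(0, 0.05, 24)
        rows -= np.median(rows)
        cols -= np.median(cols)
        table = 0.5 + rows[:, None] + cols[None, :]
        res = median_polish(table)
        assert abs(res.overall - 0.5) < 1e-6
        assert np.abs(res.row_effects - rows).max() < 1e-6
        assert np.abs(res.col_effects - cols).max() < 1e-6
        assert np.abs(res.residuals).max() < 1e-6

    def test_additive_identity(self, rng):
        table = rng.normal(size=(5, 7))
        res = median_polish(table)
        fitted = res.overall + res.row_effects[:, None] + res.col_effects[None, :]
        assert np.allclose(fitted + res.residuals, table)

    def test_idempotent_on_residuals(self, rng):
        table = rng.normal(size=(8, 10))
        res = median_polish(table)
        res2 = median_polish(res.residuals)
        assert abs(res2.overall) < 1e-5
        assert np.abs(res2.row_effects).max() < 1e-5
        assert np.abs(res2.col_effects).max() < 1e-5


class TestPolishPlate:
    def test_plate_effects_removed(self, grid_meta, rng):
        rows = rng.normal(0, 0.05, 6)
        cols = rng.normal(0, 0.05, 8)
        values = np.array(
            [[0.5 + rows[m["row"]] + cols[m["col"]]] for _, m in grid_meta.iterrows()]
        )
        wells = make_wells(values, grid_meta)
        polished, row_eff, col_eff, overall = polish_plate(wells, "f0")
        # polished values = overall + residual: the planted surface flattens
        assert np.abs(polished - polished.mean()).max() < 1e-6

    def test_single_row_plate_warns(self):
        meta = make_meta([{"plate": "P0", "well": f"w{c}", "row": 0, "col": c}
                          for c in range(5)])
        wells = make_wells(np.arange(5.0)[:, None], meta)
        with pytest.warns(UserWarning, match="single row"):
            polish_plate(wells, "f0")

    def test_polish_all_features_sets_flag(self, grid_meta, rng):
        wells = make_wells(rng.normal(0.5, 0.1, (48, 3)), grid_meta)
        out = polish(wells)
        assert out.polished
        assert out.values.shape == wells.values.shape


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------

class TestScaleUnitInterval:
    def _wells(self, values):
        meta = make_meta([{"plate": "P0", "well": f"w{i}"} for i in range(len(values))])
        return make_wells(np.asarray(values, float)[:, None], meta)

    def test_monotone_map_onto_unit_interval(self):
        wells = self._wells(np.linspace(2.0, 4.0, 21))
        out = scale_unit_interval(wells, lower_pct=0.0, upper_pct=100.0)
        scaled = out.values["f0"].to_numpy()
        assert scaled.min() == 0.0 and scaled.max() == 1.0
        assert (np.diff(scaled) > 0).all()

    def test_outlier_clipped_to_one(self):
        values = np.concatenate([np.linspace(0, 1, 50), [100.0]])
        wells = self._wells(values)
        out = scale_unit_interval(wells, lower_pct=0.5, upper_pct=99.5)
        assert out.values["f0"].iloc[-1] == 1.0

    def test_percentile_oracle_on_uniform_draws(self, rng):
        values = rng.uniform(0, 1, 1000)
        wells = self._wells(values)
        out = scale_unit_interval(wells, lower_pct=0.5, upper_pct=99.5)
        scaled = out.values["f0"].to_numpy()
        assert scaled.min() == 0.0 and scaled.max() == 1.0
        lo, hi = np.percentile(values, [0.5, 99.5])
        interior = (values > lo) & (values < hi)
        oracle = (values[interior] - lo) / (hi - lo)
        assert np.allclose(scaled[interior], oracle)

    def test_zero_variance_feature_flagged_at_half(self):
        wells = self._wells(np.full(10, 3.3))
        out = scale_unit_interval(wells)
        assert (out.values["f0"] == 0.5).all()
        assert any(f == "f0" for f, _ in out.flagged_features)


# ---------------------------------------------------------------------------
# feature filter cascade
# ---------------------------------------------------------------------------

def _build_filter_fixture(rng, n_drugs=20, n_reps=4, n_ctrl=8):
    """30 features: 10 clean, 5 noisy, 5 irreproducible, 5 inert, 5 redundant."""
    features = (
        [f"clean{i}" for i in range(10)]
        + [f"noisy{i}" for i in range(5)]
        + [f"irrep{i}" for i in range(5)]
        + [f"inert{i}" for i in range(5)]
        + [f"redund{i}" for i in range(5)]
    )
    drug_signal = {f: rng.normal(0.5, 0.2, n_drugs) for f in features}
    inert_signal = {f: rng.normal(0.5, 0.004, n_drugs) for f in features}

    rows, values = [], []
    for plate in ("P0", "P1"):
        for i in range(n_ctrl):
            rows.append({"plate": plate, "well": f"ctrl{i}", "role": "control",
                         "row": 0, "col": i})
            vals = {}
            for f in features:
                base, sd = 0.5, 0.01
                if f.startswith("noisy"):
                    sd = 0.25
                vals[f] = rng.normal(base, sd)
            values.append(vals)
    for d in range(n_drugs):
        for rep in range(1, n_reps + 1):
            plate = "P0" if rep <= n_reps // 2 else "P1"
            rows.append({"plate": plate, "well": f"d{d}r{rep}", "role": "single",
                         "drug_a": f"drug{d}", "replicate": rep,
                         "row": 1 + rep, "col": d})
            vals = {}
            for f in features:
                if f.startswith("clean"):
                    vals[f] = drug_signal[f][d] + rng.normal(0, 0.01)
                elif f.startswith("redund"):
                    # scaled-down copy of a clean feature: correlated, smaller z
                    twin = f"clean{int(f[-1])}"
                    vals[f] = 0.5 + 0.5 * (drug_signal[twin][d] - 0.5) + rng.normal(0, 0.003)
                elif f.startswith("noisy"):
                    vals[f] = rng.normal(0.5, 0.25)
                elif f.startswith("irrep"):
                    vals[f] = rng.normal(0.5, 0.2)      # no drug dependence
                else:                                    # inert: tiny but reproducible
                    vals[f] = inert_signal[f][d] + rng.normal(0, 0.001)
            values.append(vals)
    meta = make_meta(rows)
    return make_wells(pd.DataFrame(values).to_numpy(), meta, features=features)


class TestFilterFeatures:
    def test_planted_cascade_recovery(self, rng):
        wells = _build_filter_fixture(rng)
        sel = filter_features(wells, NormalizeConfig())
        assert sorted(sel.retained) == sorted(f"clean{i}" for i in range(10))
        diag = sel.diagnostics
        for i in range(5):
            assert diag.loc[f"noisy{i}", "removed_at"] == "i:control_cv"
            assert diag.loc[f"irrep{i}", "removed_at"] == "ii:replicate_corr"
            assert diag.loc[f"inert{i}", "removed_at"] == "iii:no_effect"
            assert diag.loc[f"redund{i}", "removed_at"] == "iv:redundant"

    def test_rerun_on_retained_output_is_stable(self, rng):
        wells = _build_filter_fixture(rng)
        sel = filter_features(wells)
        again = filter_features(wells.subset_features(sel.retained))
        assert sorted(again.retained) == sorted(sel.retained)

    def test_duplicate_pruning_removes_smaller_effect(self, rng):
        wells = _build_filter_fixture(rng)
        sel = filter_features(wells)
        # every redundant twin was pruned in favour of its clean original
        assert all(f.startswith("clean") for f in sel.retained)

    def test_too_few_controls_aborts(self, rng):
        wells = _build_filter_fixture(rng)
        keep = [i for i, (idx, m) in enumerate(wells.meta.iterrows())
                if not (m["role"] == "control" and idx[0] == "P0" and idx[1] != "ctrl0")]
        sub = make_wells(
            wells.values.iloc[keep].to_numpy(), wells.meta.iloc[keep],
            features=wells.features,
        )
        with pytest.raises(ValueError, match="control wells"):
            filter_features(sub)


# ---------------------------------------------------------------------------
# perturbation filter
# ---------------------------------------------------------------------------

def _drug_meta(counts, n_ctrl=4, ctrl_count=100):
    rows = [{"plate": "P0", "well": f"c{i}", "role": "control",
             "cell_count": ctrl_count} for i in range(n_ctrl)]
    for drug, series in counts.items():
        for t, c in enumerate(series, start=1):
            rows.append({"plate": "P0", "well": f"{drug}r{t}", "role": "single",
                         "drug_a": drug, "replicate": t, "time_order": t,
                         "cell_count": c})
    meta = make_meta(rows)
    values = np.full((len(meta), 2), 0.5)
    return make_wells(values, meta)


class TestFilterPerturbations:
    def test_cell_count_boundary(self):
        wells = _drug_meta({"d": [29, 30, 31, 40, 50, 60]})
        validity = filter_perturbations(wells)
        assert not validity.wells.loc[("P0", "dr1"), "valid"]
        assert validity.wells.loc[("P0", "dr2"), "valid"]

    def test_flat_counts_are_stable(self):
        wells = _drug_meta({"d": [80, 80, 80, 80, 80, 80]})
        validity = filter_perturbations(wells)
        row = validity.drugs.loc["d"]
        assert row["slope"] == pytest.approx(0.0)
        assert row["valid"]

    def test_declining_counts_against_least_squares_oracle(self):
        counts = [100, 90, 80, 70, 60, 50]
        wells = _drug_meta({"d": counts}, ctrl_count=100)
        validity = filter_perturbations(wells)
        row = validity.drugs.loc["d"]
        x = np.arange(1, 7)
        y = np.array(counts) / 100.0
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        assert row["slope"] == pytest.approx(slope)
        assert row["rel_count_diff"] == pytest.approx(0.5)
        # declining counts: slope negative, so the drug is retained
        assert row["valid"]

    def test_rising_counts_with_large_diff_fail(self):
        # normalized slope (2.0 - 1.0) over 6 points: ~0.2 > 0.05, diff 50%
        wells = _drug_meta({"d": [100, 120, 140, 160, 180, 200]}, ctrl_count=100)
        validity = filter_perturbations(wells)
        assert not validity.drugs.loc["d", "valid"]

    def test_single_time_point_not_assessed(self):
        wells = _drug_meta({"d": [100, 100, 100]})
        wells.meta.loc[wells.meta["role"] == "single", "time_order"] = 1
        validity = filter_perturbations(wells)
        row = validity.drugs.loc["d"]
        assert not row["stability_assessed"]
        assert row["valid"]

    def test_under_replicated_drug_fails(self):
        wells = _drug_meta({"d": [100, 100]})
        validity = filter_perturbations(wells)
        assert not validity.drugs.loc["d", "valid"]
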