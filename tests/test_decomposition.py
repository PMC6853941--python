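"""Vector decomposition, interaction taxonomy and statistical calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from perturbome.decomposition import (
    DegenerateGeometryError,
    NON_INTERACTION,
    build_ni_cloud,
    classify,
    decompose,
    derive_effect_thresholds,
    enumerate_interaction_classes,
    interaction_significance,
    EffectThresholds,
)
from perturbome._mahalanobis import pca_mahalanobis


finite_vec = st.lists(st.floats(-10, 10), min_size=3, max_size=3)


class TestDecompose:
    def test_exact_superposition_is_non_interaction(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        dec = decompose(a, b, a + b)
        assert dec.alpha == pytest.approx(1.0)
        assert dec.beta == pytest.approx(1.0)
        assert dec.gamma == pytest.approx(0.0, abs=1e-9)

    def test_pure_out_of_plane(self):
        dec = decompose(np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                        np.array([0, 0, 1.0]))
        assert dec.alpha == pytest.approx(0.0, abs=1e-12)
        assert dec.beta == pytest.approx(0.0, abs=1e-12)
        assert dec.gamma == pytest.approx(1.0)

    def test_matches_direct_minimization_oracle(self, rng):
        for _ in range(200):
            a, b, c = rng.normal(size=(3, 10))
            dec = decompose(a, b, c)

            def dist2(p):
                return np.sum((p[0] * a + p[1] * b - c) ** 2)

            opt = optimize.minimize(dist2, x0=[0.0, 0.0], method="Nelder-Mead",
                                    options={"xatol": 1e-10, "fatol": 1e-14})
            assert dec.alpha == pytest.approx(opt.x[0], abs=1e-6)
            assert dec.beta == pytest.approx(opt.x[1], abs=1e-6)
            assert dec.gamma == pytest.approx(np.sqrt(dist2(opt.x)), abs=1e-6)

    def test_reconstruction_identity(self, rng):
        a, b, c = rng.normal(size=(3, 12))
        dec = decompose(a, b, c)
        recon = dec.alpha * a + dec.beta * b + dec.gamma * dec.n_hat
        assert np.linalg.norm(c - recon) < 1e-8 * np.linalg.norm(c)

    def test_residual_orthogonal_to_plane(self, rng):
        a, b, c = rng.normal(size=(3, 8))
        dec = decompose(a, b, c)
        assert abs(dec.n_hat @ a) < 1e-8
        assert abs(dec.n_hat @ b) < 1e-8

    def test_collinear_inputs_raise_with_diagnostic(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError) as err:
            decompose(a, 2 * a, np.array([1.0, 0, 0]))
        assert err.value.projection is not None

    def test_zero_vector_raises(self):
        with pytest.raises(ValueError, match="nonzero"):
            decompose(np.zeros(3), np.ones(3), np.ones(3))

    @given(finite_vec, finite_vec, finite_vec)
    @settings(deadline=None, max_examples=100)
    def test_symmetry_swaps_alpha_beta(self, a, b, c):
        a, b, c = map(np.array, (a, b, c))
        gram = np.array([[a @ a, a @ b], [a @ b, b @ b]])
        if a @ a < 1e-4 or b @ b < 1e-4 or np.linalg.cond(gram) > 1e6:
            return
        d1 = decompose(a, b, c)
        d2 = decompose(b, a, c)
        assert d1.alpha == pytest.approx(d2.beta, rel=1e-6, abs=1e-8)
        assert d1.beta == pytest.approx(d2.alpha, rel=1e-6, abs=1e-8)
        assert d1.gamma == pytest.approx(d2.gamma, rel=1e-6, abs=1e-8)

    @given(finite_vec, finite_vec, finite_vec, st.floats(0.1, 10))
    @settings(deadline=None, max_examples=100)
    def test_scale_covariance(self, a, b, c, lam):
        a, b, c = map(np.array, (a, b, c))
        gram = np.array([[a @ a, a @ b], [a @ b, b @ b]])
        if a @ a < 1e-4 or b @ b < 1e-4 or np.linalg.cond(gram) > 1e6:
            return
        d1 = decompose(a, b, c)
        d2 = decompose(lam * a, b, c)
        assert d2.alpha == pytest.approx(d1.alpha / lam, rel=1e-5, abs=1e-7)


class TestTaxonomy:
    def test_twenty_seven_subspaces(self):
        tax = enumerate_interaction_classes()
        assert tax["n_subspaces"] == 27

    def test_dimension_histogram(self):
        tax = enumerate_interaction_classes()
        assert tax["dimension_histogram"] == {0: 1, 1: 6, 2: 12, 3: 8}

    def test_eighteen_classes_with_category_split(self):
        tax = enumerate_interaction_classes()
        assert tax["n_classes"] == 18
        assert tax["category_counts"] == {
            "undirected": 2, "uni-directional": 8, "bi-directional": 8,
        }

    def test_non_interaction_class_present(self):
        tax = enumerate_interaction_classes()
        keys = {(c["state_a"], c["state_b"], c["emergent"]) for c in tax["classes"]}
        assert ("unchanged", "unchanged", False) in keys
        assert len(keys) == 18


class TestNICloud:
    def test_cardinality(self, rng):
        cloud = build_ni_cloud(rng.normal(size=(3, 5)), rng.normal(size=(3, 5)),
                               0.5 + rng.normal(0, 0.01, (10, 5)), np.full(5, 0.5))
        assert len(cloud) == 90

    def test_degenerate_cloud_collapses_to_sum(self):
        a = np.tile([1.0, 2.0], (3, 1))
        b = np.tile([0.5, -1.0], (3, 1))
        ref = np.array([0.4, 0.6])
        controls = np.tile(ref, (4, 1))  # controls exactly at the reference
        cloud = build_ni_cloud(a, b, controls, ref)
        assert np.allclose(cloud.points, [1.5, 1.0])

    def test_covariance_matches_moment_oracle(self, rng):
        d, sigma = 6, 0.05
        a, b = rng.normal(0, 1, (2, d))
        reps_a = a + rng.normal(0, sigma, (40, d))
        reps_b = b + rng.normal(0, sigma, (40, d))
        ref = np.full(d, 0.5)
        cloud = build_ni_cloud(reps_a, reps_b, np.tile(ref, (5, 1)), ref)
        # controls at reference: cloud variance is the two replicate noises
        trace = np.trace(np.atleast_2d(cloud.covariance))
        assert trace == pytest.approx(2 * sigma**2 * d, rel=0.35)

    def test_empty_controls_raise(self, rng):
        with pytest.raises(ValueError, match="control"):
            build_ni_cloud(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)),
                           np.empty((0, 3)), np.full(3, 0.5))


class TestInteractionSignificance:
    def test_centroid_scores_zero(self, rng):
        cloud = build_ni_cloud(rng.normal(size=(5, 4)), rng.normal(size=(5, 4)),
                               0.5 + rng.normal(0, 0.02, (8, 4)), np.full(4, 0.5))
        d_i, sig, _ = interaction_significance(cloud.mean, cloud)
        assert d_i < 1.0
        assert not sig

    def test_one_dimensional_z_score_reduction(self, rng):
        from perturbome.decomposition import NICloud
        points = rng.normal(2.0, 0.5, (400, 1))
        cloud = NICloud(points=points, n_reps_a=20, n_reps_b=20, n_controls=1)
        x = points.mean() + points.std(ddof=0)
        d_i, _, k = interaction_significance(np.array([x]), cloud, 0.999)
        assert k == 1
        assert d_i == pytest.approx(1.0, rel=0.05)

    def test_chi_square_tail_under_superposition_null(self, rng):
        # i.i.d. superposition-null cloud: D_I^2 is chi-square(k)
        from perturbome.decomposition import NICloud
        d = 8
        mean = rng.normal(0, 0.1, d)
        sd = np.linspace(0.8, 1.2, d) * 0.05
        points = mean + rng.normal(0, sd, (4000, d))
        cloud = NICloud(points=points, n_reps_a=1, n_reps_b=1, n_controls=1)
        metric = pca_mahalanobis(points, 0.9)
        obs = mean + rng.normal(0, sd, (1000, d))
        frac = np.mean(metric.distance(obs) > 3.0)
        expected = stats.chi2.sf(9.0, metric.n_components)
        assert frac == pytest.approx(expected, abs=0.02)


class TestEffectThresholds:
    def test_degenerate_spread_gives_zero_band(self):
        thr = derive_effect_thresholds({"d": [(1.0, 1.0, 0.0)] * 6}, min_pairs=5)
        lo, hi = thr["d"].alpha_band
        assert lo == hi == 1.0

    def test_mad_band_hand_computation(self):
        triples = [(a, 1.0, 0.0) for a in (0.8, 0.9, 1.0, 1.1, 1.2)]
        thr = derive_effect_thresholds({"d": triples}, mad_k=2.0, min_pairs=5)
        assert thr["d"].alpha_band == pytest.approx((0.8, 1.2))

    def test_gamma_threshold_is_sample_maximum(self, rng):
        gammas = rng.uniform(0, 0.5, 10)
        triples = [(1.0, 1.0, g) for g in gammas]
        thr = derive_effect_thresholds({"d": triples}, min_pairs=5)
        assert thr["d"].t_gamma == pytest.approx(gammas.max())

    def test_few_pairs_fall_back_to_global(self):
        thr = derive_effect_thresholds(
            {"rich": [(1.0, 1.0, 0.1)] * 8, "poor": [(2.0, 2.0, 0.9)]},
            min_pairs=5,
        )
        assert thr["poor"].fallback
        assert not thr["rich"].fallback


def _bands(center=1.0, width=0.1, t_gamma=0.1):
    return EffectThresholds(
        alpha_band=(center - width, center + width),
        beta_band=(center - width, center + width),
        t_gamma=t_gamma, n_pairs=10,
    )


class TestClassify:
    def _dec(self, alpha, beta, gamma, d=4):
        from perturbome.decomposition import Decomposition
        return Decomposition(alpha=alpha, beta=beta, gamma=gamma,
                             n_hat=np.zeros(d), reconstruction_error=0.0)

    def test_ni_point_yields_no_edges(self):
        call = classify(("A", "B"), self._dec(1.0, 1.0, 0.0), d_i=10.0,
                        thresholds_a=_bands(), thresholds_b=_bands())
        assert call.interaction_class == NON_INTERACTION
        assert call.edges == []

    def test_unidirectional_negative_edge(self):
        call = classify(("A", "B"), self._dec(0.2, 1.0, 0.0), d_i=10.0,
                        thresholds_a=_bands(), thresholds_b=_bands())
        assert call.category == "uni-directional"
        (edge,) = call.edges
        assert (edge.source, edge.target, edge.kind, edge.directed) == ("B", "A", "negative", True)

    def test_insignificant_pair_is_non_interaction(self):
        call = classify(("A", "B"), self._dec(5.0, 5.0, 5.0), d_i=1.0,
                        thresholds_a=_bands(), thresholds_b=_bands())
        assert not call.is_interaction

    def test_exhaustive_grid_matches_region_oracle(self):
        t = 0.1
        thr = _bands(width=t, t_gamma=t)
        for da in (-0.5, 0.0, 0.5):
            for db in (-0.5, 0.0, 0.5):
                for g in (0.0, 0.5):
                    call = classify(("A", "B"), self._dec(1 + da, 1 + db, g),
                                    d_i=10.0, thresholds_a=thr, thresholds_b=thr)
                    exp_a = ("decreased" if da < -t else
                             "increased" if da > t else "unchanged")
                    exp_b = ("decreased" if db < -t else
                             "increased" if db > t else "unchanged")
                    assert call.interaction_class == (exp_a, exp_b, g > t)

    def test_emergent_gate_uses_larger_gamma_threshold(self):
        call = classify(("A", "B"), self._dec(1.0, 1.0, 0.3), d_i=10.0,
                        thresholds_a=_bands(t_gamma=0.1),
                        thresholds_b=_bands(t_gamma=0.4))
        assert not call.emergent  # 0.3 < max(0.1, 0.4)


class TestParameterRecovery:
    def test_coefficients_unbiased_and_rmse_shrinks_with_noise(self, rng):
        d = 10
        a, b = rng.normal(0, 1, (2, d))
        n_hat = rng.normal(0, 1, d)
        basis = np.linalg.qr(np.column_stack([a, b]))[0]
        n_hat -= basis @ (basis.T @ n_hat)
        n_hat /= np.linalg.norm(n_hat)
        truth = (0.4, 1.6, 0.8)
        rmses = []
        for noise in (0.2, 0.05, 0.01):
            errs = []
            for _ in range(200):
                c = truth[0] * a + truth[1] * b + truth[2] * n_hat \
                    + rng.normal(0, noise, d)
                dec = decompose(a, b, c)
                errs.append([dec.alpha - truth[0], dec.beta - truth[1],
                             dec.gamma - truth[2]])
            rmses.append(np.sqrt(np.mean(np.square(errs))))
        assert rmses[0] > rmses[1] > rmses[2]
        assert rmses[2] < 0.02
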