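"""Polarity-invariant clustering, k selection and template matching."""

import numpy as np
import pytest

import eegmicrostates as em
from eegmicrostates.cluster import ClusterConfig


def orthonormal_maps(n_channels, k, seed=0):
    """k mean-zero orthonormal topographies (exactly uncorrelated)."""
    return em.make_templates(n_channels, k, seed=seed, orthogonalize=True).maps


class TestSpatialCorr:
    def test_self_correlation_is_one(self, rng):
        u = rng.normal(size=20)
        assert em.spatial_corr(u, u) == pytest.approx(1.0)

    def test_polarity_ignored_on_sign_flip(self, rng):
        u = rng.normal(size=20)
        assert em.spatial_corr(u, -u) == pytest.approx(1.0)
        assert em.spatial_corr(u, -u, ignore_polarity=False) == pytest.approx(-1.0)

    def test_orthogonal_maps_correlate_at_zero(self):
        maps = orthonormal_maps(30, 2)
        assert abs(em.spatial_corr(maps[0], maps[1])) < 1e-12

    def test_zero_variance_map_rejected(self):
        with pytest.raises(ValueError):
            em.spatial_corr(np.ones(10), np.arange(10.0))


class TestModifiedKmeans:
    def test_noiseless_two_template_recovery(self, rng):
        truth = orthonormal_maps(30, 2, seed=1)
        signs = rng.choice([-1.0, 1.0], size=40)
        maps = truth[rng.integers(0, 2, 40)] * signs[:, None]
        sol = em.modified_kmeans(maps, 2, ClusterConfig(n_restarts=5, rng_seed=0))
        C = np.abs(sol.templates.maps @ truth.T)
        assert np.allclose(C.max(axis=1), 1.0)
        assert sol.gev_total == pytest.approx(1.0)

    def test_k1_template_is_dominant_eigenvector_and_gev_matches_oracle(self, rng):
        maps = rng.normal(size=(25, 12))
        sol = em.modified_kmeans(maps, 1, ClusterConfig(n_restarts=1, rng_seed=0))
        X = maps - maps.mean(axis=1, keepdims=True)
        Xn = X / np.linalg.norm(X, axis=1, keepdims=True)  # one vote per map
        evals, evecs = np.linalg.eigh(Xn.T @ Xn)
        dominant = evecs[:, -1]
        assert abs(em.spatial_corr(sol.templates.maps[0], dominant)) == pytest.approx(1.0)
        # brute-force GEV: sum gfp^2 corr^2 / sum gfp^2 over all maps
        gfp = X.std(axis=1)
        corr = np.array([em.spatial_corr(m, sol.templates.maps[0]) for m in X])
        oracle = np.sum(gfp**2 * corr**2) / np.sum(gfp**2)
        assert sol.gev_total == pytest.approx(oracle)

    def test_noisy_three_template_recovery(self, rng):
        truth = orthonormal_maps(40, 3, seed=2)
        idx = rng.integers(0, 3, 60)
        noise = rng.normal(0, 0.1, (60, 40))
        maps = truth[idx] * rng.choice([-1.0, 1.0], 60)[:, None] + noise
        sol = em.modified_kmeans(maps, 3, ClusterConfig(n_restarts=10, rng_seed=4))
        C = np.abs(sol.templates.maps @ truth.T)
        assert (C.max(axis=1) > 0.95).all()

    def test_k_larger_than_map_count_rejected(self, rng):
        with pytest.raises(ValueError):
            em.modified_kmeans(rng.normal(size=(3, 10)), 4)

    def test_gev_nondecreasing_in_k(self, rng):
        truth = orthonormal_maps(30, 4, seed=3)
        maps = truth[rng.integers(0, 4, 80)] + rng.normal(0, 0.3, (80, 30))
        cfg = ClusterConfig(n_restarts=10, rng_seed=5)
        gevs = [em.modified_kmeans(maps, k, cfg).gev_total for k in (2, 3, 4, 5)]
        assert all(b >= a - 1e-3 for a, b in zip(gevs, gevs[1:]))

    def test_templates_invariant_under_input_sign_flips(self, rng):
        truth = orthonormal_maps(30, 2, seed=4)
        maps = truth[rng.integers(0, 2, 30)] + rng.normal(0, 0.05, (30, 30))
        cfg = ClusterConfig(n_restarts=5, rng_seed=6)
        sol_a = em.modified_kmeans(maps, 2, cfg)
        flips = rng.choice([-1.0, 1.0], 30)[:, None]
        sol_b = em.modified_kmeans(maps * flips, 2, cfg)
        C = np.abs(sol_a.templates.maps @ sol_b.templates.maps.T)
        # same templates up to sign and label order
        assert np.allclose(np.sort(C.max(axis=1)), 1.0, atol=1e-6)

    def test_k_equal_to_distinct_maps_explains_everything(self, rng):
        distinct = orthonormal_maps(20, 4, seed=5)
        maps = np.repeat(distinct, 5, axis=0)
        sol = em.modified_kmeans(maps, 4, ClusterConfig(n_restarts=5, rng_seed=7))
        assert sol.gev_total == pytest.approx(1.0)


class TestSelectOptimalK:
    def test_five_template_data_selects_five(self, templates110, rng):
        idx = rng.integers(0, 5, 400)
        maps = (templates110.maps[idx] * rng.choice([-1.0, 1.0], 400)[:, None]
                + rng.normal(0, 0.25 / np.sqrt(110), (400, 110)))
        cfg = ClusterConfig(k_range=range(2, 9), n_restarts=8, rng_seed=0)
        k_star, sols = em.select_optimal_k(maps, cfg)
        assert k_star == 5
        assert sols[5].criteria_scores is not None

    def test_two_template_data_selects_two(self, rng):
        truth = orthonormal_maps(40, 2, seed=6)
        maps = (truth[rng.integers(0, 2, 200)]
                + rng.normal(0, 0.15 / np.sqrt(40), (200, 40)))
        cfg = ClusterConfig(k_range=range(2, 7), n_restarts=8, rng_seed=1)
        k_star, _ = em.select_optimal_k(maps, cfg)
        assert k_star == 2

    def test_degenerate_single_template_warns_and_returns_min_k(self, rng):
        base = rng.normal(size=20)
        maps = np.outer(rng.choice([-1.0, 1.0], 30) * rng.uniform(0.5, 2, 30), base)
        with pytest.warns(UserWarning):
            k_star, _ = em.select_optimal_k(maps, ClusterConfig(k_range=(2, 3, 4),
                                                                n_restarts=2))
        assert k_star == 2


class TestGroupTemplates:
    def test_identical_subject_sets_recovered_exactly(self, rng):
        truth = orthonormal_maps(30, 3, seed=7)
        sets = [em.TemplateSet(maps=truth.copy()) for _ in range(5)]
        sol = em.group_templates(sets, 3, ClusterConfig(n_restarts=5, rng_seed=2))
        C = np.abs(sol.templates.maps @ truth.T)
        assert np.allclose(np.sort(C.max(axis=1)), 1.0)
        assert sol.templates.level == "group"

    def test_many_subjects_one_truth(self, templates110, rng):
        sets = []
        for _ in range(20):
            jitter = rng.normal(0, 0.15 / np.sqrt(110), (5, 110))
            sets.append(em.TemplateSet(maps=templates110.maps + jitter))
        sol = em.group_templates(sets, 5, ClusterConfig(n_restarts=10, rng_seed=3))
        C = np.abs(sol.templates.maps @ templates110.maps.T)
        assert (C.max(axis=1) > 0.95).all()

    def test_pooled_gev_bounded_by_best_subset(self, rng):
        truth = orthonormal_maps(30, 3, seed=8)
        make = lambda n: [em.TemplateSet(maps=truth + rng.normal(0, 0.1, (3, 30)))
                          for _ in range(n)]
        a, b = make(4), make(4)
        cfg = ClusterConfig(n_restarts=8, rng_seed=4)
        gev_a = em.group_templates(a, 3, cfg).gev_total
        gev_b = em.group_templates(b, 3, cfg).gev_total
        gev_pool = em.group_templates(a + b, 3, cfg).gev_total
        assert gev_pool <= max(gev_a, gev_b) + 0.05

    def test_heterogeneous_channel_counts_rejected(self, rng):
        sets = [em.TemplateSet(maps=rng.normal(size=(2, 10))),
                em.TemplateSet(maps=rng.normal(size=(2, 12)))]
        with pytest.raises(ValueError):
            em.group_templates(sets, 2)

    def test_single_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            em.group_templates([em.TemplateSet(maps=rng.normal(size=(2, 10)))], 2)


class TestMatchTemplates:
    def test_permuted_sign_flipped_set_recovered(self, templates110, rng):
        perm = rng.permutation(5)
        flips = rng.choice([-1.0, 1.0], 5)[:, None]
        other = em.TemplateSet(maps=templates110.maps[perm] * flips)
        pairs, corrs = em.match_templates(templates110, other)
        assert np.allclose(corrs, 1.0)
        # the permutation is recovered: pair i of set_a maps to position of i in perm
        recovered = {a: b for a, b in pairs}
        for i, lab in enumerate(templates110.labels):
            assert recovered[lab] == other.labels[int(np.flatnonzero(perm == i)[0])]

    def test_independent_sets_correlate_below_09(self):
        a = em.make_templates(110, 5, seed=10)
        b = em.make_templates(110, 5, seed=20)
        _, corrs = em.match_templates(a, b)
        assert corrs.mean() < 0.9

    def test_k1_gives_single_pair(self, rng):
        u = rng.normal(size=15)
        v = rng.normal(size=15)
        a = em.TemplateSet(maps=u[None, :], labels=["A"])
        b = em.TemplateSet(maps=v[None, :], labels=["A"])
        pairs, corrs = em.match_templates(a, b)
        assert len(pairs) == 1
        assert corrs[0] == pytest.approx(em.spatial_corr(u, v))

    def test_unequal_k_rejected(self, rng):
        a = em.TemplateSet(maps=rng.normal(size=(2, 10)))
        b = em.TemplateSet(maps=rng.normal(size=(3, 10)))
        with pytest.raises(ValueError):
            em.match_templates(a, b)
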