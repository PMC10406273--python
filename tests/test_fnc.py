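"""Functional network connectivity: correlation oracles, window
bookkeeping, state clustering and the FDR-controlled group contrast."""

import itertools as it

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from parc5d.fnc import (FncMatrix, WindowSpec, assign_states, dfnc_windows,
                        features_to_matrix, fit_states, fnc_group_test,
                        matrix_to_features, n_windows, occupancy_ratio,
                        sfnc_matrix, sfnc_pair)

RNG = np.random.default_rng(31)


def _rand_maps(k=3, shape=(4, 4, 3, 5)):
    return [RNG.random(shape) for _ in range(k)]


class TestSfnc:
    def test_self_correlation_is_one(self):
        m = RNG.random((3, 3, 3, 4))
        assert sfnc_pair(m, m.copy()) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        m = RNG.random((3, 3, 3, 4))
        assert sfnc_pair(m, -m + 0.7) == pytest.approx(-1.0)

    def test_matches_bruteforce_formula(self):
        """Explicit-loop covariance / sigma sigma on < 10^3 elements."""
        a = RNG.random((4, 4, 4, 10))
        b = RNG.random((4, 4, 4, 10))
        got = sfnc_pair(a, b)
        av, bv = a.ravel(), b.ravel()
        n = av.size
        ma = sum(av) / n
        mb = sum(bv) / n
        cov = sum((x - ma) * (y - mb) for x, y in zip(av, bv)) / n
        sa = (sum((x - ma) ** 2 for x in av) / n) ** 0.5
        sb = (sum((y - mb) ** 2 for y in bv) / n) ** 0.5
        assert got == pytest.approx(cov / (sa * sb), rel=1e-10)

    def test_mask_restricts_support(self):
        a, b = RNG.random((3, 3, 3, 4)), RNG.random((3, 3, 3, 4))
        mask = np.zeros((3, 3, 3), bool)
        mask[0] = True
        got = sfnc_pair(a, b, mask=mask)
        expect = np.corrcoef(a[0].ravel(), b[0].ravel())[0, 1]
        assert got == pytest.approx(expect, rel=1e-10)

    def test_zero_variance_reported_missing(self):
        a = np.zeros((2, 2, 2, 3))
        b = RNG.random((2, 2, 2, 3))
        assert np.isnan(sfnc_pair(a, b))

    def test_matrix_symmetry_unit_diagonal(self):
        maps = _rand_maps(4)
        m = sfnc_matrix(maps).data
        np.testing.assert_allclose(m, m.T, rtol=1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert np.nanmax(np.abs(m)) <= 1.0 + 1e-12

    def test_duplicate_maps_all_ones(self):
        m = RNG.random((3, 3, 3, 4))
        out = sfnc_matrix([m, m.copy(), m.copy()]).data
        np.testing.assert_allclose(out, 1.0)

    def test_k2_offdiagonal_equals_pair(self):
        a, b = RNG.random((3, 3, 3, 4)), RNG.random((3, 3, 3, 4))
        m = sfnc_matrix([a, b]).data
        assert m[0, 1] == pytest.approx(sfnc_pair(a, b), rel=1e-12)

    def test_domain_block_structure_on_synthetic_study(self, small_templates):
        """Within-domain map correlations exceed cross-domain ones on a
        seeded study (domain-block FNC structure)."""
        from parc5d.synthetic import (observed_score_maps, render_subject,
                                      study_mask)
        cfg, templates = small_templates
        mask = study_mask(templates)
        dom = {t.network_id: t.domain for t in templates}
        rows = []
        for i in range(4):
            _, subj = render_subject(templates, cfg, "control", i)
            rows.append(sfnc_matrix(observed_score_maps(subj, cfg),
                                    mask=mask).data)
        r = np.mean(rows, axis=0)
        within = [r[a - 1, b - 1] for a, b in it.combinations(dom, 2)
                  if dom[a] == dom[b]]
        cross = [r[a - 1, b - 1] for a, b in it.combinations(dom, 2)
                 if dom[a] != dom[b]]
        assert np.mean(within) > np.mean(cross) + 0.2


class TestWindows:
    def test_reference_layout(self):
        """T=150, length 30, overlap 10 (stride 20) gives 7 windows."""
        assert n_windows(150, WindowSpec(30, 10)) == 7

    def test_single_window_limit_equals_sfnc(self):
        maps = _rand_maps(3, (3, 3, 3, 6))
        spec = WindowSpec(window_length=6, overlap=3)
        wins = dfnc_windows(maps, spec)
        assert len(wins) == 1
        np.testing.assert_allclose(wins[0].data, sfnc_matrix(maps).data,
                                   rtol=1e-12)

    def test_maximal_overlap(self):
        assert n_windows(20, WindowSpec(5, 4)) == 16  # T - L + 1

    def test_window_content(self):
        maps = _rand_maps(2, (3, 3, 3, 10))
        spec = WindowSpec(window_length=4, overlap=2)
        wins = dfnc_windows(maps, spec)
        assert len(wins) == 4
        manual = sfnc_matrix([m[..., 2:6] for m in maps]).data
        np.testing.assert_allclose(wins[1].data, manual, rtol=1e-12)

    def test_too_short_scan_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            n_windows(5, WindowSpec(30, 10))

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            WindowSpec(window_length=10, overlap=10)
        with pytest.raises(ValueError):
            WindowSpec(window_length=10, overlap=0)

    @given(st.integers(2, 60), st.integers(2, 30), st.integers(1, 29))
    def test_count_formula_matches_enumeration(self, t_total, length,
                                               overlap):
        """floor((T-L)/stride)+1 equals brute-force enumeration of window
        start positions for every valid spec."""
        if not (1 <= overlap < length <= t_total):
            return
        spec = WindowSpec(length, overlap)
        # enumerate consecutive starts explicitly
        count, s = 0, 0
        while s + length <= t_total:
            count += 1
            s += spec.stride
        assert n_windows(t_total, spec) == count


class TestStates:
    def _two_blob_windows(self, n_per=30, k=4, sep=6.0):
        base_a = features_to_matrix(RNG.uniform(-0.2, 0.2, k * (k - 1) // 2),
                                    k)
        base_b = base_a + sep * features_to_matrix(
            np.ones(k * (k - 1) // 2), k) * (1 - np.eye(k))
        wins, truth = [], []
        for i in range(n_per):
            for j, base in enumerate((base_a, base_b)):
                noise = RNG.normal(0, 0.05, (k, k))
                m = base + (noise + noise.T) / 2
                np.fill_diagonal(m, 1.0)
                wins.append(FncMatrix(m))
                truth.append(j)
        return wins, np.array(truth)

    def test_elbow_picks_two_for_two_blobs(self):
        wins, truth = self._two_blob_windows()
        model = fit_states(wins, k_candidates=range(1, 7), seed=0)
        assert model.k == 2
        labels = assign_states(wins, model)
        agreement = max(np.mean(labels == truth),
                        np.mean(labels == 1 - truth))
        assert agreement == 1.0

    def test_k1_centroid_is_mean(self):
        wins, _ = self._two_blob_windows(n_per=10)
        model = fit_states(wins, k_candidates=[1], seed=0)
        feats = np.stack([matrix_to_features(w.data) for w in wins])
        np.testing.assert_allclose(model.centroids[0], feats.mean(0),
                                   rtol=1e-6)

    def test_seeded_determinism(self):
        wins, _ = self._two_blob_windows(n_per=15)
        a = fit_states(wins, seed=3)
        b = fit_states(wins, seed=3)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.k == b.k

    def test_centroid_window_assigned_to_itself(self):
        wins, _ = self._two_blob_windows(n_per=10)
        model = fit_states(wins, k_candidates=[2], seed=0)
        centro = FncMatrix(features_to_matrix(model.centroids[1],
                                              model.n_networks))
        assert assign_states([centro], model)[0] == 1

    def test_tie_goes_to_lowest_state(self):
        model_feats = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        from parc5d.fnc import StateModel
        model = StateModel(k=2, centroids=model_feats, inertia_curve={},
                           n_networks=3, seed=0)
        equidistant = FncMatrix(features_to_matrix(np.zeros(3), 3))
        assert assign_states([equidistant], model)[0] == 0

    def test_inertia_nonincreasing_in_k(self):
        wins, _ = self._two_blob_windows(n_per=20)
        model = fit_states(wins, k_candidates=range(1, 7), seed=0)
        curve = [model.inertia_curve[k] for k in sorted(model.inertia_curve)]
        assert all(a >= b - 1e-9 for a, b in zip(curve, curve[1:]))

    def test_too_few_windows_rejected(self):
        wins, _ = self._two_blob_windows(n_per=1)
        with pytest.raises(ValueError, match="windows"):
            fit_states(wins, k_candidates=[10], seed=0)


class TestOccupancy:
    def test_counting(self):
        np.testing.assert_allclose(occupancy_ratio(np.array([0, 0, 1, 1]), 2),
                                   [0.5, 0.5])
        np.testing.assert_allclose(occupancy_ratio(np.array([2, 2, 2]), 4),
                                   [0, 0, 1, 0])

    def test_sums_to_one(self):
        labels = RNG.integers(0, 5, size=37)
        assert occupancy_ratio(labels, 5).sum() == pytest.approx(1.0)

    def test_relabeling_permutes_components(self):
        labels = RNG.integers(0, 3, size=24)
        perm = np.array([2, 0, 1])
        a = occupancy_ratio(labels, 3)
        b = occupancy_ratio(perm[labels], 3)
        np.testing.assert_allclose(b[perm], a)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            occupancy_ratio(np.array([], dtype=int), 2)


class TestGroupTest:
    def _matrices(self, arr):
        return [FncMatrix(features_to_matrix(v, 4)) for v in arr]

    def test_identical_groups_empty_mask(self):
        x = RNG.random((6, 6))
        t, sig, _ = fnc_group_test(self._matrices(x), self._matrices(x))
        assert not sig.any()
        np.testing.assert_array_equal(t, 0)

    def test_bh_subset_of_raw(self):
        """BH-significant cells are a subset of raw p < q cells."""
        xc = RNG.normal(0, 1, (10, 6))
        xs = RNG.normal(0.8, 1, (10, 6))
        from scipy import stats
        t, sig, adj = fnc_group_test(self._matrices(xc), self._matrices(xs))
        _, praw = stats.ttest_ind(xc, xs, axis=0, equal_var=False)
        iu = np.triu_indices(4, 1)
        assert np.all(adj[iu] >= praw - 1e-12)
        assert not np.any(sig[iu] & ~(praw < 0.05))

    def test_strong_effect_detected_symmetrically(self):
        xc = RNG.normal(0, 0.05, (12, 6))
        xs = xc + 1.0
        t, sig, _ = fnc_group_test(self._matrices(xc), self._matrices(xs))
        assert sig[np.triu_indices(4, 1)].all()
        np.testing.assert_array_equal(sig, sig.T)
        assert not np.diag(sig).any()

    def test_group_size_guard(self):
        x = RNG.random((1, 6))
        with pytest.raises(ValueError, match=">=2"):
            fnc_group_test(self._matrices(x), self._matrices(RNG.random((5, 6))))
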