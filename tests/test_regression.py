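"""Mass-univariate regression and cluster permutation: OLS oracle, cluster
invariances, p-value floor, and an independent cross-check against MNE."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from cploc import regression, synth_eeg
from cploc.regression import cluster_test, fit_betas, select_epochs, zscore


def _meta(n, n_first=2, n_probe=2, seed=0):
    rng = np.random.default_rng(seed)
    is_first = np.zeros(n, bool)
    is_first[:n_first] = True
    is_probe = np.zeros(n, bool)
    is_probe[-n_probe:] = True
    return pd.DataFrame(
        {
            "is_first": is_first,
            "is_probe": is_probe,
            "pu": rng.gamma(3, 2, n),
            "su": rng.gamma(2, 1.5, n),
        }
    )


def _grid_adjacency(n_ch):
    """Chain adjacency over channels."""
    band = sparse.diags([True] * (n_ch - 1), 1, shape=(n_ch, n_ch), dtype=bool)
    return (band + band.T).tocsr()


class TestSelectAndZscore:
    def test_excludes_first_and_probe(self):
        meta = _meta(10)
        mask = select_epochs(meta)
        assert mask.sum() == 6
        assert not mask[:2].any() and not mask[-2:].any()

    def test_three_sound_trial_keeps_middle_only(self):
        meta = pd.DataFrame(
            {"is_first": [True, False, False], "is_probe": [False, False, True],
             "pu": [1, 2, 3.0], "su": [3, 2, 1.0]}
        )
        assert np.array_equal(select_epochs(meta), [False, True, False])

    def test_all_excluded_raises(self):
        meta = pd.DataFrame(
            {"is_first": [True, False], "is_probe": [False, True],
             "pu": [1, 2.0], "su": [1, 2.0]}
        )
        with pytest.raises(ValueError):
            select_epochs(meta)

    def test_zscore_population_convention(self):
        z = zscore(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(z, [-1.22474487, 0.0, 1.22474487])
        assert z.mean() == pytest.approx(0.0, abs=1e-15)

    def test_zscore_constant_raises(self):
        with pytest.raises(regression.DegeneratePredictorError):
            zscore(np.full(5, 3.0))


class TestFitBetas:
    def test_exact_recovery_of_planted_coefficient(self):
        """A datapoint that is a pure multiple of z(PU) yields beta_PU = 1
        (the EEG side is z-scored too, absorbing the scale) and beta_SU = 0
        exactly, because the response lies in the span of the PU regressor."""
        meta = _meta(60, seed=1)
        mask = select_epochs(meta)
        z_pu = zscore(meta["pu"].to_numpy()[mask])
        rng = np.random.default_rng(2)
        data = rng.standard_normal((2, 3, 60))
        data[0, 1, mask] = 0.5 * z_pu
        betas = fit_betas(data, meta)
        assert betas.shape == (2, 2, 3)
        assert betas[0, 0, 1] == pytest.approx(1.0, abs=1e-10)
        assert betas[1, 0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_betas_match_normal_equations_oracle(self):
        """OLS against an explicit normal-equations solve, <= 1e-8."""
        rng = np.random.default_rng(3)
        meta = _meta(80, seed=4)
        mask = select_epochs(meta)
        data = rng.standard_normal((4, 10, 80))
        betas = fit_betas(data, meta)
        z_pu = zscore(meta["pu"].to_numpy()[mask])
        z_su = zscore(meta["su"].to_numpy()[mask])
        X = np.column_stack([np.ones_like(z_pu), z_pu, z_su])
        XtX_inv = np.linalg.inv(X.T @ X)
        for ch in range(4):
            for t in range(10):
                y = zscore(data[ch, t, mask])
                b = XtX_inv @ X.T @ y
                assert abs(betas[0, ch, t] - b[1]) < 1e-8
                assert abs(betas[1, ch, t] - b[2]) < 1e-8

    def test_collinear_predictors_rejected(self):
        meta = _meta(30, seed=5)
        meta["su"] = 2.0 * meta["pu"] + 0.3
        with pytest.raises(regression.CollinearityError):
            fit_betas(np.random.default_rng(0).standard_normal((2, 4, 30)), meta)

    def test_noise_betas_shrink_with_epochs(self):
        rng = np.random.default_rng(6)
        small = _meta(40, seed=7)
        big = _meta(800, seed=7)
        b_small = fit_betas(rng.standard_normal((2, 5, 40)), small)
        b_big = fit_betas(rng.standard_normal((2, 5, 800)), big)
        assert np.abs(b_big).mean() < np.abs(b_small).mean()


def _planted_maps(n_subj=10, n_ch=8, n_t=40, effect=1.0, seed=0, t_slice=slice(10, 20)):
    rng = np.random.default_rng(seed)
    maps = 0.3 * rng.standard_normal((n_subj, n_ch, n_t))
    maps[:, 2:5, t_slice] += effect
    return maps


class TestClusterTest:
    times = np.arange(40) / 250.0  # 0..156 ms

    def test_null_maps_give_no_clusters(self):
        rng = np.random.default_rng(1)
        maps = rng.standard_normal((8, 6, 30)) * 0.2
        cs = cluster_test(
            maps, _grid_adjacency(6), np.arange(30) / 250.0, (0.0, 0.12),
            n_perm=100, seed=0,
        )
        assert all(c.p > 0.05 for c in cs.clusters)

    def test_planted_effect_found(self):
        maps = _planted_maps(effect=2.0)
        cs = cluster_test(
            maps, _grid_adjacency(8), self.times, (0.0, 0.15), n_perm=200, seed=1
        )
        sig = cs.significant()
        assert len(sig) >= 1
        assert sig[0].sign == 1
        # p-values follow (1 + exceedances) / (n_perm + 1) against the
        # stored max-mass null, and never undercut the attainable floor
        for c in cs.clusters:
            expect = (1 + np.sum(cs.null_max_mass >= abs(c.mass))) / 201.0
            assert c.p == pytest.approx(expect)
            assert c.p >= 1.0 / 201.0

    def test_min_p_floor_attained(self):
        """An effect far above the noise reaches exactly p = 1/(n_perm+1):
        no sign-flip draw can match the observed cluster mass."""
        rng = np.random.default_rng(12)
        maps = 0.05 * rng.standard_normal((12, 6, 20))
        maps[:, 1:4, 5:15] += 5.0
        t = np.arange(20) / 250.0
        cs = cluster_test(
            maps, _grid_adjacency(6), t, (0.0, 0.08), n_perm=1000, seed=13
        )
        assert min(c.p for c in cs.clusters) == pytest.approx(1.0 / 1001.0)

    def test_duration_filter_at_250hz(self):
        """A one-sample (4 ms) cluster is dropped; two samples (8 ms) kept."""
        base = np.zeros((8, 4, 20))
        rng = np.random.default_rng(2)
        base += 0.05 * rng.standard_normal(base.shape)
        one = base.copy()
        one[:, 1, 10] += 5.0
        two = base.copy()
        two[:, 1, 10:12] += 5.0
        t = np.arange(20) / 250.0
        adj = _grid_adjacency(4)
        cs1 = cluster_test(one, adj, t, (0.0, 0.08), n_perm=50, seed=3)
        cs2 = cluster_test(two, adj, t, (0.0, 0.08), n_perm=50, seed=3)
        assert len(cs1.clusters) == 0
        assert len(cs2.clusters) >= 1

    def test_sign_symmetry(self):
        maps = _planted_maps(effect=1.5, seed=4)
        adj = _grid_adjacency(8)
        cs_pos = cluster_test(maps, adj, self.times, (0.0, 0.15), n_perm=100, seed=5)
        cs_neg = cluster_test(-maps, adj, self.times, (0.0, 0.15), n_perm=100, seed=5)
        assert len(cs_pos.clusters) == len(cs_neg.clusters)
        for a, b in zip(cs_pos.clusters, cs_neg.clusters):
            assert a.sign == -b.sign
            assert a.mass == pytest.approx(-b.mass)
            assert a.p == b.p

    def test_channel_reordering_invariance(self):
        """Permuting channels (data + adjacency) relabels but does not change
        cluster membership."""
        maps = _planted_maps(effect=1.5, seed=6)
        adj = _grid_adjacency(8).toarray()
        perm = np.random.default_rng(7).permutation(8)
        maps_p = maps[:, perm, :]
        adj_p = adj[np.ix_(perm, perm)]
        cs = cluster_test(
            maps, sparse.csr_matrix(adj), self.times, (0.0, 0.15), n_perm=50, seed=8
        )
        cs_p = cluster_test(
            maps_p, sparse.csr_matrix(adj_p), self.times, (0.0, 0.15), n_perm=50, seed=8
        )
        inv = np.empty(8, int)
        inv[perm] = np.arange(8)

        def key(c, back=None):
            ch = c.ch_idx if back is None else back[c.ch_idx]
            return sorted(zip(ch.tolist(), c.t_idx.tolist()))

        orig = sorted(key(c) for c in cs.clusters)
        permd = sorted(key(c, perm) for c in cs_p.clusters)
        assert orig == permd

    def test_paired_contrast_detects_condition_difference(self):
        rng = np.random.default_rng(9)
        a = 0.3 * rng.standard_normal((10, 8, 40))
        b = a + 0.1 * rng.standard_normal((10, 8, 40))
        b[:, 2:5, 10:20] += 1.5
        cs = regression.cluster_test_paired(
            b, a, _grid_adjacency(8), self.times, (0.0, 0.15), n_perm=200, seed=10
        )
        sig = cs.significant()
        assert len(sig) >= 1 and sig[0].sign == 1

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            cluster_test(
                np.zeros((4, 4, 10)), _grid_adjacency(4), np.arange(10) / 250.0,
                (0.0, 0.03),
            )

    def test_window_outside_data(self):
        with pytest.raises(ValueError):
            cluster_test(
                np.zeros((8, 4, 10)), _grid_adjacency(4), np.arange(10) / 250.0,
                (1.0, 2.0),
            )


class TestMneCrossCheck:
    def test_cluster_partition_matches_mne(self):
        """Observed t-map, suprathreshold partition and cluster masses agree
        with MNE's spatio-temporal cluster test at the same threshold."""
        mne = pytest.importorskip("mne")
        from mne.stats import spatio_temporal_cluster_1samp_test

        maps = _planted_maps(n_subj=12, effect=1.2, seed=11)
        n_subj, n_ch, n_t = maps.shape
        times = np.arange(n_t) / 250.0
        adj = _grid_adjacency(n_ch)
        cs = cluster_test(
            maps, adj, times, (times[0], times[-1]), n_perm=100, seed=0,
            min_dur_ms=0.0,
        )
        X = maps.transpose(0, 2, 1)  # mne wants (obs, times, space)
        t_mne, clusters, _, _ = spatio_temporal_cluster_1samp_test(
            X, threshold=cs.threshold, n_permutations=50,
            adjacency=sparse.coo_matrix(adj), tail=0, seed=0, out_type="indices",
            verbose="error",
        )
        assert np.allclose(cs.tmap, t_mne.T, rtol=1e-8)
        mine = sorted(
            tuple(sorted(zip(c.ch_idx.tolist(), c.t_idx.tolist())))
            for c in cs.clusters
        )
        theirs = sorted(
            tuple(sorted(zip(sp.tolist(), tt.tolist()))) for tt, sp in clusters
        )
        assert mine == theirs
        my_masses = sorted(round(c.mass, 6) for c in cs.clusters)
        mne_masses = sorted(round(float(t_mne.T[sp, tt].sum()), 6) for tt, sp in clusters)
        assert my_masses == mne_masses
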