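"""Comparison methods and their known relationships to the demixing model."""

import numpy as np
import pytest

import dpca
from dpca.baselines import (classical_tuning, doc_axes, factorial_lda,
                            marg_pca_pinv, pca_baseline, tdr)
from dpca.core import rrr_solve
from dpca.evaluation import demixing_index, explained_variance
from dpca.marginalization import (CovarianceSet, decompose,
                                  marginalized_covariances)
from dpca.synthetic import _project_to_label


class TestPcaBaseline:
    def test_full_rank_explains_everything(self, small_fit):
        *_, psth, mset, noise, _ = small_fit
        bm = pca_baseline(psth, q=psth.n_neurons)
        rep = explained_variance(bm.decoders @ psth.matrix(), psth)
        assert abs(rep.total_r2 - 1.0) < 1e-10

    def test_rank_one_data_single_pc(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(6)
        course = rng.standard_normal((3, 2, 8))
        course -= course.mean()
        arr = u[:, None, None, None] * course[None]
        arr -= arr.mean(axis=(1, 2, 3), keepdims=True)
        psth = dpca.PsthTensor(values=arr, time=np.arange(8, dtype=float),
                               centered=True, means=np.zeros(6))
        bm = pca_baseline(psth, q=3)
        sv = bm.meta["singular_values"]
        assert sv[1] < 1e-10 * sv[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_pca_explains_at_least_as_much_as_dpca(self, seed):
        """PCA is variance-optimal: at equal q its cumulative R^2 is an
        upper bound for the demixing components'."""
        data, _ = dpca.generate_population(N=12, S=3, Q=2, T=12, K=3,
                                           snr=1.0, seed=seed)
        psth = dpca.compute_psths(data)
        mset = decompose(psth)
        model = dpca.fit(psth, mset, q_per_label=2)
        q = model.n_components
        F, D, _ = model.stacked()
        X = psth.matrix()
        r2_dpca = 1 - np.sum((X - F @ (D @ X)) ** 2) / np.sum(X ** 2)
        U = pca_baseline(psth, q=q).encoders
        r2_pca = 1 - np.sum((X - U @ (U.T @ X)) ** 2) / np.sum(X ** 2)
        assert r2_pca >= r2_dpca - 1e-10


def _disjoint_label_psth(k_per_label=2, T=16, seed=1):
    """Population whose marginalization subspaces occupy disjoint neurons."""
    rng = np.random.default_rng(seed)
    S, Q = 3, 2
    blocks = []
    for lab in ("t", "st", "dt", "sdt"):
        rows = np.zeros((k_per_label, S, Q, T))
        for j in range(k_per_label):
            rows[j] = _project_to_label(rng.standard_normal((S, Q, T)), lab)
        blocks.append(rows)
    arr = np.concatenate(blocks, axis=0)
    N = arr.shape[0]
    return dpca.PsthTensor(values=arr, time=np.arange(T, dtype=float),
                           centered=True, means=np.zeros(N))


class TestMargPcaPinv:
    def test_orthogonal_label_subspaces_give_transpose_decoders(self):
        psth = _disjoint_label_psth(k_per_label=2)
        mset = decompose(psth)
        bm = marg_pca_pinv(mset, k=2)
        np.testing.assert_allclose(bm.decoders, bm.encoders.T, atol=1e-8)

    def test_approximates_demixing_solution_on_separated_data(self):
        data, truth = dpca.generate_population(N=40, S=3, Q=2, T=20, K=10,
                                               snr=5.0, seed=2)
        psth = dpca.compute_psths(data)
        mset = decompose(psth)
        model = dpca.fit(psth, mset, q_per_label=1)
        bm = marg_pca_pinv(mset, k=1)
        X = psth.matrix()
        for i, lab in enumerate(bm.axis_labels):
            a = bm.decoders[i] @ X
            b = model.decoders[lab][0] @ X
            assert abs(np.corrcoef(a, b)[0, 1]) > 0.9

    def test_too_small_k_hurts_demixing(self):
        """With 3 latents per marginalization, k = 1 leaves the pseudo-inverse
        decoders exposed to leakage from the unmodelled latents of the other
        marginalizations: the leading component per label demixes worse than
        with k = 3."""
        v1, v3 = [], []
        for seed in range(3, 9):
            data, _ = dpca.generate_population(N=12, S=3, Q=2, T=10, K=10,
                                               snr=1000.0, seed=seed,
                                               n_latents_per_label=3)
            psth = dpca.compute_psths(data)
            mset = decompose(psth)

            def leading_demix(k):
                bm = marg_pca_pinv(mset, k=k)
                idx = [bm.axis_labels.index(lab) for lab in mset.labels]
                return np.mean([demixing_index(bm.decoders[i], mset)
                                for i in idx])

            v1.append(leading_demix(1))
            v3.append(leading_demix(3))
        assert np.mean(v1) < np.mean(v3) - 0.02

    def test_overcomplete_stacking_warns(self):
        psth = _disjoint_label_psth(k_per_label=1)
        mset = decompose(psth)
        with pytest.warns(UserWarning, match="underdetermined"):
            marg_pca_pinv(mset, k=10)


class TestTdr:
    def test_single_parameter_axis_aligns_with_demixing_axis(self):
        data, _ = dpca.generate_population(N=25, S=4, Q=2, T=20, K=5,
                                           snr=50.0, seed=4,
                                           n_latents_per_label={"st": 1})
        psth = dpca.compute_psths(data)
        mset = decompose(psth)
        model = dpca.fit(psth, mset, q_per_label=1,
                         noise=dpca.estimate_noise_covariance(data))
        bm = tdr(psth, stimulus_values=np.arange(4), decision_values=[0, 1])
        i = bm.axis_labels.index("st")
        cos = abs(bm.decoders[i] @ model.decoders["st"][0]
                  / np.linalg.norm(model.decoders["st"][0]))
        assert cos > 0.95

    def test_axes_orthonormal(self, small_fit):
        *_, psth, mset, noise, _ = small_fit
        S, Q = psth.values.shape[1:3]
        bm = tdr(psth, np.arange(S), np.arange(Q))
        G = bm.decoders @ bm.decoders.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-10)

    def test_stacking_order_changes_axes(self, small_fit):
        *_, psth, mset, noise, _ = small_fit
        S, Q = psth.values.shape[1:3]
        a = tdr(psth, np.arange(S), np.arange(Q),
                order=("st", "dt", "sdt"))
        b = tdr(psth, np.arange(S), np.arange(Q),
                order=("sdt", "dt", "st"))
        d_a = a.decoders[a.axis_labels.index("dt")]
        d_b = b.decoders[b.axis_labels.index("dt")]
        assert abs(abs(d_a @ d_b) - 1) > 1e-3

    def test_absent_effect_flagged(self):
        data, _ = dpca.generate_population(N=10, S=3, Q=2, T=10, K=2,
                                           noise_sd=0.0, seed=5,
                                           n_latents_per_label={"st": 1})
        psth = dpca.compute_psths(data)
        with pytest.warns(UserWarning, match="absent effect"):
            bm = tdr(psth, np.arange(3), [0, 1])
        assert "dt" in bm.meta["degenerate"]

    def test_collinear_parametrization_rejected(self, small_fit):
        *_, psth, mset, noise, _ = small_fit
        S, Q = psth.values.shape[1:3]
        with pytest.raises(ValueError, match="collinear"):
            tdr(psth, np.zeros(S), np.arange(Q))


class TestFactorialLda:
    def test_two_isotropic_classes_axis_is_mean_difference(self):
        rng = np.random.default_rng(6)
        mu = np.array([2.0, -1.0, 0.5])
        n = 4000
        X = np.concatenate([mu[:, None] + rng.standard_normal((3, n)),
                            -mu[:, None] + rng.standard_normal((3, n))],
                           axis=1)
        X -= X.mean(axis=1, keepdims=True)
        cents = np.concatenate([np.tile(X[:, :n].mean(1)[:, None], n),
                                np.tile(X[:, n:].mean(1)[:, None], n)],
                               axis=1)
        m = X.shape[1]
        cset = CovarianceSet(total=X @ X.T / m,
                             per_label={"cls": cents @ cents.T / m})
        bm = factorial_lda(cset, "cls", q=1)
        cos = abs(bm.decoders[0] @ mu) / np.linalg.norm(mu)
        assert cos > 0.99

    def test_lda_equalizes_spacing_dpca_preserves_it(self):
        """Three classes with very unequal centroid gaps but comparable
        within-class (Mahalanobis) separations: the LDA projection spaces
        the classes nearly evenly, the demixing projection keeps the true
        gap ratio."""
        rng = np.random.default_rng(0)
        cents = np.array([[0, 0], [0, 0.8], [4.0, 0.4]]).T
        n_per = 300
        sd = np.array([0.75, 0.15])
        pts, lab = [], []
        for c in range(3):
            pts.append(cents[:, c][None, :]
                       + rng.standard_normal((n_per, 2)) * sd)
            lab += [c] * n_per
        X = np.vstack(pts).T
        X -= X.mean(axis=1, keepdims=True)
        lab = np.array(lab)
        cent_of = np.stack([X[:, lab == c].mean(1) for c in range(3)],
                           axis=1)
        Xphi = cent_of[:, lab]
        n = X.shape[1]
        C = X @ X.T / n
        Cphi = Xphi @ Xphi.T / n
        cset = CovarianceSet(total=C, per_label={"cls": Cphi})

        lda = factorial_lda(cset, "cls", q=2)
        Cm = C - Cphi
        scale = np.sqrt(np.einsum("in,nm,im->i", lda.decoders, Cm,
                                  lda.decoders))
        D_lda = lda.decoders / scale[:, None]    # within-metric scaling
        _, D_dpca, _ = rrr_solve(Xphi, X, q=2)

        def gap_ratio(D):
            P = D @ cent_of
            d12 = np.linalg.norm(P[:, 1] - P[:, 0])
            d23 = np.linalg.norm(P[:, 2] - P[:, 1])
            return d12 / d23

        true_ratio = (np.linalg.norm(cent_of[:, 1] - cent_of[:, 0])
                      / np.linalg.norm(cent_of[:, 2] - cent_of[:, 1]))
        assert true_ratio < 0.3
        assert gap_ratio(D_lda) > 0.6            # near-equal spacing
        assert abs(gap_ratio(D_dpca) - true_ratio) < 0.1

    def test_eigenvalues_invariant_under_rotation(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((4, 4))
        C_between = A @ A.T
        B = rng.standard_normal((4, 4))
        C_within = B @ B.T + 4 * np.eye(4)
        cset = CovarianceSet(total=C_between + C_within,
                             per_label={"x": C_between})
        e1 = factorial_lda(cset, "x", q=4).meta["eigenvalues"]
        R = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        cset_r = CovarianceSet(total=R @ (C_between + C_within) @ R.T,
                               per_label={"x": R @ C_between @ R.T})
        e2 = factorial_lda(cset_r, "x", q=4).meta["eigenvalues"]
        np.testing.assert_allclose(np.sort(e1), np.sort(e2), rtol=1e-8)

    def test_singular_within_requires_ridge(self):
        cset = CovarianceSet(total=np.eye(3),
                             per_label={"x": np.eye(3)})
        with pytest.raises(ValueError, match="ridge"):
            factorial_lda(cset, "x", q=1)
        bm = factorial_lda(cset, "x", q=1, ridge=1e-3)
        assert np.all(np.isfinite(bm.decoders))


class TestDocAxes:
    def test_zero_second_covariance_reduces_to_pca_of_first(self):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((5, 30))
        C1 = A @ A.T / 30
        cset = CovarianceSet(total=C1,
                             per_label={"a": C1, "b": np.zeros((5, 5))})
        bm = doc_axes(cset, ("a", "b"))
        w, V = np.linalg.eigh(C1)
        top = V[:, np.argmax(w)]
        assert abs(bm.decoders[0] @ top) > 1 - 1e-10
        assert bm.axis_labels[0] == "a"

    def test_label_swap_flips_eigenvalue_signs(self):
        rng = np.random.default_rng(9)
        A = rng.standard_normal((4, 20))
        B = rng.standard_normal((4, 20))
        cset = CovarianceSet(total=np.eye(4),
                             per_label={"a": A @ A.T, "b": B @ B.T})
        e_ab = doc_axes(cset, ("a", "b")).meta["eigenvalues"]
        e_ba = doc_axes(cset, ("b", "a")).meta["eigenvalues"]
        np.testing.assert_allclose(np.sort(e_ab), np.sort(-e_ba),
                                   atol=1e-10)

    def test_oblique_subspaces_demix_worse_than_dpca(self):
        """When label subspaces are non-orthogonal, the single orthogonal
        axis set of the difference-of-covariances method demixes worse than
        the unconstrained decoders."""
        rng = np.random.default_rng(10)
        S, Q, T, N = 3, 2, 16, 6
        z1 = _project_to_label(rng.standard_normal((S, Q, T)), "st")
        z2 = _project_to_label(rng.standard_normal((S, Q, T)), "t")
        w1 = np.zeros(N)
        w1[0] = 1.0
        w2 = 0.9 * w1 + np.sqrt(1 - 0.81) * np.eye(N)[1]   # oblique
        arr = (w1[:, None, None, None] * z1[None]
               + w2[:, None, None, None] * z2[None])
        psth = dpca.PsthTensor(values=arr, time=np.arange(T, dtype=float),
                               centered=True, means=np.zeros(N))
        mset = decompose(psth)
        cset = marginalized_covariances(mset)
        bm = doc_axes(cset, ("st", "t"))
        model = dpca.fit(psth, mset, q_per_label={"st": 1, "t": 1})
        i_st = bm.axis_labels.index("st")
        doc_idx = demixing_index(bm.decoders[i_st], mset)
        dpca_idx = demixing_index(model.decoders["st"][0], mset)
        assert dpca_idx > doc_idx + 0.01


class TestClassicalTuning:
    def test_null_data_false_positive_rate_near_alpha(self):
        rng = np.random.default_rng(11)
        vals = rng.standard_normal((60, 3, 2, 6, 8))
        data = dpca.TrialTensor(values=vals,
                                trial_counts=np.full((60, 3, 2), 8),
                                time=np.arange(6, dtype=float))
        res = classical_tuning(data, alpha=0.05)
        for eff in ("stimulus", "decision", "interaction"):
            rate = (res.p_values[eff] < 0.05).mean()
            assert abs(rate - 0.05) < 0.025, eff

    def test_one_factor_two_level_effect_size_is_signed_r2(self):
        """With a single two-level factor the signed partial omega^2 is close
        to the signed R^2 between rate and factor level (asymptotically)."""
        rng = np.random.default_rng(12)
        k = 2000
        vals = np.full((1, 2, 1, 1, k), np.nan)
        y0 = rng.standard_normal(k) - 1.0
        y1 = rng.standard_normal(k) + 1.0
        vals[0, 0, 0, 0] = y0
        vals[0, 1, 0, 0] = y1
        # duplicate the decision axis so the design is 2x2 with no decision
        # or interaction effect
        vals2 = np.concatenate([vals, vals], axis=2)
        data = dpca.TrialTensor(values=vals2,
                                trial_counts=np.full((1, 2, 2), k),
                                time=np.zeros(1))
        res = classical_tuning(data)
        y = np.concatenate([y0, y1, y0, y1])
        g = np.repeat([0.0, 1.0, 0.0, 1.0], k)
        r = np.corrcoef(y, g)[0, 1]
        signed_r2 = np.sign(r) * r ** 2
        assert res.effect_sizes["stimulus"][0, 0] == pytest.approx(
            signed_r2, abs=0.01)

    def test_identical_tuned_neurons_population_average(self):
        """All neurons identical and stimulus-tuned: the population average
        equals each neuron's centered PSTH."""
        rng = np.random.default_rng(13)
        S, Q, T, K, N = 3, 2, 5, 6, 8
        base = np.linspace(-1, 1, S)[:, None, None] * np.ones((S, Q, T))
        vals = np.empty((N, S, Q, T, K))
        noise = 0.05 * rng.standard_normal((S, Q, T, K))
        for n in range(N):
            vals[n] = base[..., None] + noise
        data = dpca.TrialTensor(values=vals,
                                trial_counts=np.full((N, S, Q), K),
                                time=np.arange(T, dtype=float))
        res = classical_tuning(data)
        psth = dpca.compute_psths(data, center=True)
        comp = res.population_average(psth, "stimulus", time_index=0)
        np.testing.assert_allclose(comp, psth.values[0], atol=1e-10)

    def test_single_trial_rejected(self):
        data, _ = dpca.generate_population(N=3, S=2, Q=2, T=4, K=1, seed=0)
        with pytest.raises(ValueError, match="2 trials"):
            classical_tuning(data)


def test_benchmark_demixing_ordering():
    """On a standard synthetic suite the mean demixing index orders
    dPCA >= per-marginalization PCA >= {TDR, DOC}."""
    scores = {"dpca": [], "margpca": [], "tdr": [], "doc": []}
    for seed in range(3):
        data, _ = dpca.generate_population(N=40, S=3, Q=2, T=20, K=5,
                                           snr=2.0, seed=100 + seed)
        psth = dpca.compute_psths(data)
        mset = decompose(psth)
        cset = marginalized_covariances(mset)
        model = dpca.fit(psth, mset,
                         noise=dpca.estimate_noise_covariance(data),
                         q_per_label=1)
        scores["dpca"].append(np.mean(
            [demixing_index(model.decoders[lab][0], mset)
             for lab in model.decoders]))
        bm = marg_pca_pinv(mset, k=1)
        scores["margpca"].append(np.mean(
            [demixing_index(bm.decoders[i], mset)
             for i in range(bm.decoders.shape[0])]))
        bt = tdr(psth, np.arange(3), np.arange(2))
        scores["tdr"].append(np.mean(
            [demixing_index(bt.decoders[i], mset)
             for i in range(bt.decoders.shape[0])]))
        bd = doc_axes(cset, ("st", "t"))
        scores["doc"].append(np.mean(
            [demixing_index(bd.decoders[i], mset) for i in range(2)]))
    means = {k: np.mean(v) for k, v in scores.items()}
    assert means["dpca"] >= means["margpca"] - 1e-6
    assert means["margpca"] >= min(means["tdr"], means["doc"]) - 1e-6
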