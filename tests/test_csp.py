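import numpy as np
import pytest

from eegfusion.csp import (CSPModel, class_covariance, extract_virtual_channels,
                           fit_csp, fit_csp_ovr, project)
from eegfusion.synth import SynthConfig, generate_mi_dataset, mixing_matrix

from conftest import make_epochs


def gaussian_epochs(covs_per_class, n_trials, n_samples=500, seed=0):
    """Trials of i.i.d. Gaussian samples with per-class channel covariance."""
    rng = np.random.default_rng(seed)
    data, labels = [], []
    for k, cov in enumerate(covs_per_class):
        L = np.linalg.cholesky(cov)
        for _ in range(n_trials):
            data.append(L @ rng.standard_normal((cov.shape[0], n_samples)))
            labels.append(k)
    return make_epochs(np.stack(data), labels)


def brute_force_csp(c_pos, c_neg):
    """Independent oracle: eigendecomposition of inv(C+ + C-) @ C+."""
    evals, evecs = np.linalg.eig(np.linalg.inv(c_pos + c_neg) @ c_pos)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order].T


class TestFitCSP:
    def test_toy_diagonal_eigenvalue(self):
        # class A cov diag(4,1), class B diag(1,4); after trace
        # normalization the top generalized eigenvalue is 4/5 = 0.8
        ep = gaussian_epochs([np.diag([4.0, 1.0]), np.diag([1.0, 4.0])],
                             n_trials=300, seed=1)
        model = fit_csp(ep, 0)
        assert model.eigenvalues[0] == pytest.approx(0.8, abs=0.03)
        assert model.eigenvalues[-1] == pytest.approx(0.2, abs=0.03)

    def test_identical_distributions_half_eigenvalues(self):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        ep = gaussian_epochs([cov, cov], n_trials=300, seed=2)
        model = fit_csp(ep, 0)
        assert np.allclose(model.eigenvalues, 0.5, atol=0.05)

    def test_projected_variance_matches_eigenvalues(self):
        ep = gaussian_epochs([np.diag([4.0, 1.0]), np.diag([1.0, 4.0])],
                             n_trials=400, seed=3)
        model = fit_csp(ep, 0)
        # normalized variance pairs of filter outputs ~ (lambda, 1-lambda)
        for j in range(2):
            w = model.W[j]
            var = {k: np.mean([
                (w @ t) @ (w @ t) / np.trace(t @ t.T)
                for t in ep.data[ep.labels == k]]) for k in (0, 1)}
            frac = var[0] / (var[0] + var[1])
            assert frac == pytest.approx(model.eigenvalues[j], abs=0.05)

    def test_too_few_trials_rejected(self):
        ep = gaussian_epochs([np.eye(2), np.eye(2)], n_trials=1)
        with pytest.raises(ValueError, match="2 trials"):
            fit_csp(ep, 0)

    def test_simultaneous_diagonalization(self, small_binary):
        model = fit_csp(small_binary, 0)
        c0 = class_covariance(small_binary.data[small_binary.labels == 0])
        c1 = class_covariance(small_binary.data[small_binary.labels != 0])
        for c in (c0, c1):
            d = model.W @ c @ model.W.T
            off = d - np.diag(np.diag(d))
            assert np.abs(off).max() < 1e-8

    def test_eigenvalue_pairing_sums_to_one(self, small_binary):
        model = fit_csp(small_binary, 0)
        c0 = class_covariance(small_binary.data[small_binary.labels == 0])
        c1 = class_covariance(small_binary.data[small_binary.labels != 0])
        d0 = np.diag(model.W @ c0 @ model.W.T)
        d1 = np.diag(model.W @ c1 @ model.W.T)
        assert np.allclose(d0 / (d0 + d1) + d1 / (d0 + d1), 1.0, atol=1e-10)
        assert np.allclose(d0 / (d0 + d1), model.eigenvalues, atol=1e-10)

    def test_matches_brute_force_oracle_small(self):
        # <= 6 channels: filters match an independent generalized
        # eigendecomposition up to per-row sign/scale
        ep = generate_mi_dataset(SynthConfig(
            n_classes=2, n_trials_per_class=20, n_channels=5, duration=1.0,
            erd_depth=0.6, seed=21))
        model = fit_csp(ep, 0)
        c0 = class_covariance(ep.data[ep.labels == 0])
        c1 = class_covariance(ep.data[ep.labels != 0])
        evals, W_ref = brute_force_csp(c0, c1)
        assert np.allclose(model.eigenvalues, evals, atol=1e-6)
        for w_fit, w_ref in zip(model.W, W_ref):
            cos = abs(w_fit @ w_ref) / (np.linalg.norm(w_fit) * np.linalg.norm(w_ref))
            assert cos == pytest.approx(1.0, abs=1e-6)

    def test_eigenvalues_sorted_descending(self, small_binary):
        model = fit_csp(small_binary, 1)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_recovers_ground_truth_source(self):
        cfg = SynthConfig(n_classes=2, n_trials_per_class=40, n_channels=8,
                          duration=2.0, erd_depth=0.6, snr=5.0, seed=23)
        ep = generate_mi_dataset(cfg)
        model = fit_csp(ep, 0)
        u = mixing_matrix(cfg)[:, 0]
        # source 0 has minimal variance in class 0 -> last filter row
        w = model.W[-1]
        x = np.concatenate([t for t in ep.data], axis=1)
        r = np.corrcoef(w @ x, u @ x)[0, 1]
        assert abs(r) >= 0.8


class TestOvR:
    def test_three_class_cardinality(self, three_class):
        models = fit_csp_ovr(three_class)
        assert [m.positive_class for m in models] == [0, 1, 2]

    def test_binary_returns_single_model(self, tiny_binary):
        models = fit_csp_ovr(tiny_binary)
        assert len(models) == 1

    def test_own_class_variance_ratio_highest(self):
        cfg = SynthConfig(n_classes=3, n_trials_per_class=30, n_channels=9,
                          duration=2.0, erd_depth=0.8, snr=5.0, seed=31)
        ep = generate_mi_dataset(cfg)
        models = fit_csp_ovr(ep)
        # each model's most discriminative filter separates its own class
        # better than the other models' filters do
        def ratio(model, k):
            w = model.W[-1]  # low-variance side for the positive class
            v_own = np.mean([np.var(w @ t) for t in ep.data[ep.labels == k]])
            v_rest = np.mean([np.var(w @ t) for t in ep.data[ep.labels != k]])
            return v_rest / v_own

        for k, model in enumerate(models):
            own = ratio(model, k)
            others = [ratio(m, k) for j, m in enumerate(models) if j != k]
            assert own > max(others)

    def test_class_with_single_trial_rejected(self, tiny_binary):
        ep = tiny_binary.subset(np.r_[0:10, 10:11])
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_csp_ovr(ep)


class TestProject:
    def test_identity_projection(self, rng):
        model = CSPModel(np.eye(4), np.full(4, 0.5), 0)
        e = rng.standard_normal((4, 10))
        assert np.array_equal(project(model, e), e)

    def test_zero_input(self):
        model = CSPModel(np.eye(3), np.full(3, 0.5), 0)
        assert np.all(project(model, np.zeros((3, 5))) == 0)

    def test_matches_naive_matmul(self, rng):
        W = rng.standard_normal((4, 4))
        E = rng.standard_normal((4, 10))
        model = CSPModel(W, np.full(4, 0.5), 0)
        z = project(model, E)
        naive = np.zeros((4, 10))
        for i in range(4):
            for j in range(10):
                naive[i, j] = sum(W[i, k] * E[k, j] for k in range(4))
        assert np.allclose(z, naive, atol=1e-12)

    def test_linearity(self, rng):
        W = rng.standard_normal((3, 3))
        model = CSPModel(W, np.full(3, 0.5), 0)
        e1, e2 = rng.standard_normal((2, 3, 7))
        lhs = project(model, 2 * e1 + 3 * e2)
        rhs = 2 * project(model, e1) + 3 * project(model, e2)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        model = CSPModel(np.eye(4), np.full(4, 0.5), 0)
        with pytest.raises(ValueError, match="incompatible"):
            project(model, rng.standard_normal((3, 10)))


class TestVirtualChannels:
    def test_m1_selects_first_and_last(self, small_binary):
        models = [fit_csp(small_binary, 0)]
        vc = extract_virtual_channels(models, small_binary, m=1)
        assert vc.shape == (small_binary.n_trials, 2, small_binary.n_samples)
        z = project(models[0], small_binary.data[0])
        assert np.allclose(vc[0, 0], z[0])
        assert np.allclose(vc[0, 1], z[-1])

    def test_three_models_give_six_channels(self, three_class):
        models = fit_csp_ovr(three_class)
        vc = extract_virtual_channels(models, three_class, m=1)
        assert vc.shape[1] == 6

    def test_identity_w_maps_to_physical_channels(self, tiny_binary):
        M = tiny_binary.n_channels
        model = CSPModel(np.eye(M), np.full(M, 0.5), 0)
        vc = extract_virtual_channels([model], tiny_binary, m=1)
        assert np.allclose(vc[:, 0], tiny_binary.data[:, 0])
        assert np.allclose(vc[:, 1], tiny_binary.data[:, -1])

    def test_m_too_large_rejected(self, tiny_binary):
        models = fit_csp_ovr(tiny_binary)
        with pytest.raises(ValueError, match="2m"):
            extract_virtual_channels(models, tiny_binary, m=4)
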