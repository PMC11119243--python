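import numpy as np
import pytest

from entrocsp import (
    SimConfig,
    apply_filterbank,
    band_features,
    class_covariances,
    extract_features,
    fit_csp,
    fit_multiband,
    simulate_mi_eeg,
)
from entrocsp.csp import ClassCovariances
from entrocsp.exceptions import DegenerateTrialError, ValidationError
from entrocsp.filterbank import FilterBankSpec

from conftest import random_epoched


def random_spd(rng, l):
    a = rng.normal(size=(l, l))
    m = a @ a.T + 0.1 * np.eye(l)
    return m / np.trace(m)


class TestClassCovariances:
    def test_traces_are_one(self, rng):
        ep = random_epoched(rng, m=6, l=4, n=100)
        cov = class_covariances(ep.data, ep.labels)
        assert np.trace(cov.b1) == pytest.approx(1.0)
        assert np.trace(cov.b2) == pytest.approx(1.0)

    def test_single_trial_per_class_is_normalised_covariance(self, rng):
        ep = random_epoched(rng, m=2, l=3, n=50)
        cov = class_covariances(ep.data, ep.labels)
        x1 = ep.data[0]
        expected = x1 @ x1.T / np.trace(x1 @ x1.T)
        assert np.max(np.abs(cov.b1 - expected)) < 1e-12

    def test_matches_loop_oracle(self, rng):
        ep = random_epoched(rng, m=8, l=4, n=60)
        cov = class_covariances(ep.data, ep.labels)
        for cls, b in ((1, cov.b1), (2, cov.b2)):
            acc, cnt = np.zeros((4, 4)), 0
            for m in range(8):
                if ep.labels[m] != cls:
                    continue
                c = np.zeros((4, 4))
                for i in range(4):
                    for j in range(4):
                        c[i, j] = float(np.dot(ep.data[m, i], ep.data[m, j]))
                acc += c / np.trace(c)
                cnt += 1
            assert np.max(np.abs(b - acc / cnt)) < 1e-10

    def test_missing_class_and_zero_trace_rejected(self, rng):
        ep = random_epoched(rng, m=4, l=3, n=50)
        with pytest.raises(ValidationError):
            class_covariances(ep.data, np.ones(4, dtype=int))
        ep.data[2] = 0.0
        with pytest.raises(DegenerateTrialError, match="2"):
            class_covariances(ep.data, ep.labels)


class TestFitCSP:
    def test_diagonal_case_recovers_axes_and_eigenvalues(self):
        cov = ClassCovariances(b1=np.diag([2.0, 1.0]) / 3, b2=np.diag([1.0, 2.0]) / 3)
        model = fit_csp(cov, v=1)
        assert model.eigenvalues == pytest.approx([2 / 3, 1 / 3])
        # filters align with coordinate axes (up to B-normalisation scale)
        for col, axis in ((0, 0), (1, 1)):
            w = model.w[:, col]
            assert abs(w[axis]) / np.linalg.norm(w) == pytest.approx(1.0, abs=1e-10)

    def test_equal_covariances_give_half_everywhere(self, rng):
        b = random_spd(rng, 4)
        model = fit_csp(ClassCovariances(b1=b, b2=b.copy()), v=2)
        assert model.eigenvalues == pytest.approx(np.full(4, 0.5), abs=1e-6)

    def test_rayleigh_quotient_identity(self, rng):
        for _ in range(10):
            b1, b2 = random_spd(rng, 6), random_spd(rng, 6)
            model = fit_csp(ClassCovariances(b1=b1, b2=b2), v=3, reg=0.0)
            for j in range(6):
                w = model.w[:, j]
                quot = (w @ b1 @ w) / (w @ (b1 + b2) @ w)
                assert quot == pytest.approx(model.eigenvalues[j], abs=1e-8)
                assert 0.0 - 1e-9 <= model.eigenvalues[j] <= 1.0 + 1e-9
                assert w @ (b1 + b2) @ w == pytest.approx(1.0, abs=1e-5)

    def test_class_swap_complements_eigenvalues(self, rng):
        b1, b2 = random_spd(rng, 5), random_spd(rng, 5)
        lam = fit_csp(ClassCovariances(b1=b1, b2=b2), v=2, reg=0.0).eigenvalues
        lam_swapped = fit_csp(ClassCovariances(b1=b2, b2=b1), v=2, reg=0.0).eigenvalues
        # extremes of the swapped problem mirror: lambda' = 1 - lambda
        assert np.sort(lam_swapped) == pytest.approx(np.sort(1 - lam), abs=1e-8)

    def test_sign_convention_first_nonzero_positive(self, rng):
        model = fit_csp(ClassCovariances(b1=random_spd(rng, 4), b2=random_spd(rng, 4)), v=2)
        for j in range(4):
            nz = np.flatnonzero(np.abs(model.w[:, j]) > 1e-12)
            assert model.w[nz[0], j] > 0

    def test_too_many_pairs_rejected(self, rng):
        cov = ClassCovariances(b1=random_spd(rng, 3), b2=random_spd(rng, 3))
        with pytest.raises(ValidationError):
            fit_csp(cov, v=2)

    def test_top_filter_matches_dense_ratio_search(self):
        """On 4-channel simulated data the analytic filter agrees with a
        brute-force maximiser of the class-variance Rayleigh ratio."""
        rng = np.random.default_rng(7)
        hits = 0
        for seed in range(20):
            cfg = SimConfig(
                n_channels=4, informative_channels=(0, 1, 2, 3),
                trials_per_class=30, trial_len_s=2.0, erd_ratio=0.3,
                mixing=np.array([[0.8], [0.4], [0.2], [0.4]]), seed=seed,
            )
            ep, _ = simulate_mi_eeg(cfg)
            cov = class_covariances(ep.data, ep.labels)
            w_top = fit_csp(cov, v=1).w[:, 0]
            # oracle: dense random search over unit vectors
            cand = rng.normal(size=(200_000, 4))
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            ratios = np.einsum("ij,jk,ik->i", cand, cov.b1, cand) / np.einsum(
                "ij,jk,ik->i", cand, cov.b2, cand
            )
            w_star = cand[np.argmax(ratios)]
            cos = abs(w_top @ w_star) / np.linalg.norm(w_top)
            if cos > 0.9:
                hits += 1
        assert hits == 20


class TestBandFeatures:
    def test_unit_variance_projection_gives_zero_feature(self):
        from entrocsp.csp import CSPModel

        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 2, 500))
        x /= x[0].std(axis=-1, ddof=1)[None, :, None]  # identity filters see var 1
        model = CSPModel(w=np.eye(2), eigenvalues=np.array([0.5, 0.5]), v=1)
        feats = band_features(x, model)
        assert feats == pytest.approx(np.zeros((1, 2)), abs=1e-10)

    def test_trial_scaling_shifts_feature_by_2_log_c(self, rng):
        x = rng.normal(size=(3, 4, 200))
        model = fit_csp(ClassCovariances(b1=random_spd(rng, 4), b2=random_spd(rng, 4)), v=2)
        f1 = band_features(x, model)
        f2 = band_features(3.0 * x, model)
        assert f2 - f1 == pytest.approx(np.full_like(f1, 2 * np.log(3.0)), abs=1e-10)

    def test_matches_projection_variance_oracle(self, rng):
        x = rng.normal(size=(5, 4, 120))
        model = fit_csp(ClassCovariances(b1=random_spd(rng, 4), b2=random_spd(rng, 4)), v=2)
        feats = band_features(x, model)
        for m in range(5):
            for v in range(4):
                tc = model.w[:, v] @ x[m]
                assert feats[m, v] == pytest.approx(np.log(np.var(tc, ddof=1)), abs=1e-10)


class TestMultiband:
    def test_default_bank_v2_gives_four_sets_of_four_filters(self, separable_small):
        epoched, _ = separable_small
        sub = apply_filterbank(epoched)
        model = fit_multiband(sub, v=2)
        assert len(model.models) == 4
        for m in model.models:
            assert m.w.shape == (16, 4)

    def test_single_band_matches_fit_csp(self, rng):
        ep = random_epoched(rng, m=10, l=4, n=200)
        sub = apply_filterbank(ep, FilterBankSpec(bands=((8.0, 35.0),)))
        multi = fit_multiband(sub, v=2)
        direct = fit_csp(class_covariances(sub.band(0), ep.labels), v=2)
        assert np.max(np.abs(multi.models[0].w - direct.w)) < 1e-12

    def test_channel_permutation_equivariance(self, rng):
        ep = random_epoched(rng, m=10, l=5, n=200)
        perm = rng.permutation(5)
        ep_perm = type(ep)(
            data=ep.data[:, perm, :], fs=ep.fs,
            channel_names=[ep.channel_names[i] for i in perm], labels=ep.labels,
        )
        m_a = fit_multiband(apply_filterbank(ep), v=2).models[0]
        m_b = fit_multiband(apply_filterbank(ep_perm), v=2).models[0]
        # permuting channels permutes filter rows (same sign convention may
        # flip whole columns; compare up to sign)
        for j in range(4):
            diff = np.minimum(
                np.max(np.abs(m_b.w[:, j] - m_a.w[perm, j])),
                np.max(np.abs(m_b.w[:, j] + m_a.w[perm, j])),
            )
            assert diff < 1e-8


class TestExtractFeatures:
    def test_default_geometry_is_sixteen_columns(self, separable_small):
        epoched, _ = separable_small
        sub = apply_filterbank(epoched)
        model = fit_multiband(sub, v=2)
        feats = extract_features(sub, model)
        assert feats.values.shape == (epoched.n_trials, 16)
        assert len(feats.feature_names) == 16

    def test_reduced_geometry_column_count(self, rng):
        ep = random_epoched(rng, m=8, l=4, n=200)
        sub = apply_filterbank(ep, FilterBankSpec(bands=((8.0, 13.0), (13.0, 22.0))))
        model = fit_multiband(sub, v=1)
        feats = extract_features(sub, model)
        assert feats.values.shape == (8, 4)

    def test_block_assembly_matches_band_features(self, rng):
        ep = random_epoched(rng, m=6, l=4, n=200)
        sub = apply_filterbank(ep)
        model = fit_multiband(sub, v=2)
        feats = extract_features(sub, model)
        for s in range(4):
            block = band_features(sub.band(s), model.models[s])
            assert np.array_equal(feats.values[:, 4 * s:4 * (s + 1)], block)

    def test_band_mismatch_rejected(self, rng):
        ep = random_epoched(rng, m=6, l=4, n=200)
        sub = apply_filterbank(ep)
        other = apply_filterbank(ep, FilterBankSpec(bands=((8.0, 13.0),)))
        model = fit_multiband(other, v=1)
        with pytest.raises(ValidationError):
            extract_features(sub, model)
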