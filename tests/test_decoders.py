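"""Decoder contracts: tLDA structure, xDAWN tangent-space geometry, WCBLE."""

import numpy as np
import pytest
from scipy.stats import norm
from sklearn.covariance import ledoit_wolf_shrinkage

from vsabci.decoders import (
    WCBLE,
    ToeplitzLDA,
    XdawnTangentLDA,
    crop_and_decimate,
    load_decoder,
    make_decoder,
    riemannian_mean,
    save_decoder,
    tangent_vectors,
)
from vsabci.errors import DomainError


def _shrinkage_lda_oracle(x2d, y, gamma=None):
    """Unstructured shrinkage LDA computed directly from its definition."""
    mu_t, mu_nt = x2d[y].mean(0), x2d[~y].mean(0)
    c = x2d.copy()
    c[y] -= mu_t
    c[~y] -= mu_nt
    s = c.T @ c / len(x2d)
    if gamma is None:
        gamma = ledoit_wolf_shrinkage(c, assume_centered=True)
    d = s.shape[0]
    sigma = (1 - gamma) * s + gamma * np.trace(s) / d * np.eye(d)
    w = np.linalg.solve(sigma, mu_t - mu_nt)
    b = -w @ (mu_t + mu_nt) / 2
    return w, b


class TestCropDecimate:
    def test_default_window_yields_40_samples(self, covert_epochs):
        x, layout = crop_and_decimate(covert_epochs)
        assert x.shape[1:] == (18, 40)
        assert layout.decim == 20

    def test_decim_one_preserves_values(self, covert_epochs):
        x, _ = crop_and_decimate(covert_epochs, decim=1)
        start = int(round(0.1 * covert_epochs.sfreq))
        np.testing.assert_array_equal(x, covert_epochs.data[:, :, start:start + 800])

    def test_window_outside_epoch_rejected(self, covert_epochs):
        with pytest.raises(DomainError, match="outside"):
            crop_and_decimate(covert_epochs, window_ms=(0.0, 1500.0))


class TestToeplitzLDA:
    def test_single_lag_equals_unstructured_shrinkage_lda(self):
        """With one time sample the Toeplitz constraint is vacuous."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 8, 1))
        y = np.arange(200) % 2 == 0
        x[y] += 0.5
        model = ToeplitzLDA().fit(x, y)
        w, b = _shrinkage_lda_oracle(x[:, :, 0], y)
        assert np.abs(model.coef_ - w).max() / np.abs(w).max() < 1e-6
        assert abs(model.intercept_ - b) / abs(b) < 1e-6

    def test_heldout_error_near_bayes_rate(self):
        """Two Gaussian classes with a Kronecker (block-Toeplitz) covariance:
        held-out error within 3 percentage points of the analytic Bayes error."""
        rng = np.random.default_rng(42)
        n_ch, k = 4, 3
        b_spat = np.array([[1.0, 0.5, 0.2, 0.1],
                           [0.5, 1.0, 0.5, 0.2],
                           [0.2, 0.5, 1.0, 0.5],
                           [0.1, 0.2, 0.5, 1.0]])
        t_temp = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.6], [0.3, 0.6, 1.0]])
        sigma = np.kron(t_temp, b_spat)  # lag-major blocks of channels
        delta_mu = rng.normal(0, 0.35, size=n_ch * k)
        d2 = delta_mu @ np.linalg.solve(sigma, delta_mu)
        bayes = norm.cdf(-np.sqrt(d2) / 2)
        chol = np.linalg.cholesky(sigma)

        def draw(n, target):
            z = rng.standard_normal((n, n_ch * k)) @ chol.T
            if target:
                z += delta_mu
            return z

        def to3d(z):
            return z.reshape(len(z), k, n_ch).transpose(0, 2, 1)

        x_tr = np.concatenate([draw(1000, True), draw(1000, False)])
        y_tr = np.array([True] * 1000 + [False] * 1000)
        model = ToeplitzLDA().fit(to3d(x_tr), y_tr)
        x_te = np.concatenate([draw(2000, True), draw(2000, False)])
        y_te = np.array([True] * 2000 + [False] * 2000)
        err = np.mean((model.decision_function(to3d(x_te)) > 0) != y_te)
        assert abs(err - bayes) < 0.03

    def test_duplicating_epochs_keeps_weights(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, 5, 4))
        y = np.arange(60) % 2 == 0
        m1 = ToeplitzLDA(shrinkage=0.1).fit(x, y)
        m2 = ToeplitzLDA(shrinkage=0.1).fit(
            np.concatenate([x, x]), np.concatenate([y, y])
        )
        np.testing.assert_allclose(m1.coef_, m2.coef_, rtol=1e-10)

    def test_covariance_block_toeplitz_and_spd(self, covert_epochs):
        x, _ = crop_and_decimate(covert_epochs)
        m = ToeplitzLDA().fit(x, covert_epochs.labels)
        assert np.linalg.eigvalsh(m.cov_).min() > 0
        n_ch, k = x.shape[1], x.shape[2]
        blocks = m.cov_.reshape(k, n_ch, k, n_ch)
        # equal-lag blocks are identical by construction
        np.testing.assert_allclose(blocks[1, :, 0, :], blocks[2, :, 1, :], atol=1e-9)

    def test_score_contracts(self, covert_epochs):
        x, _ = crop_and_decimate(covert_epochs)
        y = covert_epochs.labels
        m = ToeplitzLDA().fit(x, y)
        s = m.decision_function(x)
        assert s[y].mean() > s[~y].mean()
        zero = np.zeros((1,) + x.shape[1:])
        assert np.isclose(m.decision_function(zero)[0], m.intercept_)
        with pytest.raises(DomainError, match="layout"):
            m.decision_function(x[:, :4, :])

    def test_single_class_rejected(self):
        x = np.zeros((4, 2, 2))
        with pytest.raises(DomainError):
            ToeplitzLDA().fit(x, np.ones(4, dtype=bool))


class TestXdawnTangent:
    def test_tangent_dimension_identity(self, covert_epochs):
        """Augmented dimension d = 3 * n_filters; vectors have d(d+1)/2."""
        m = XdawnTangentLDA(n_filters=4).fit_epochs(covert_epochs)
        d = 12
        covs = m._augmented_covs(crop_and_decimate(covert_epochs)[0][:5])
        assert covs.shape[1:] == (d, d)
        tv = tangent_vectors(covs, m.ref_mean_)
        assert tv.shape[1] == d * (d + 1) // 2

    def test_augmented_covariances_spd(self, covert_epochs):
        m = XdawnTangentLDA().fit_epochs(covert_epochs)
        covs = m._augmented_covs(crop_and_decimate(covert_epochs)[0])
        assert min(np.linalg.eigvalsh(c).min() for c in covs) > 0

    def test_riemannian_mean_of_identical_matrices(self):
        c = np.diag([2.0, 0.5, 1.0])
        covs = np.stack([c] * 7)
        np.testing.assert_allclose(riemannian_mean(covs), c, atol=1e-10)

    def test_tangent_vectors_at_own_mean_average_to_zero(self):
        rng = np.random.default_rng(0)
        covs = []
        for _ in range(10):
            a = rng.standard_normal((4, 4))
            covs.append(a @ a.T + 4 * np.eye(4))
        covs = np.stack(covs)
        g = riemannian_mean(covs)
        tv = tangent_vectors(covs, g)
        # the Karcher mean zeroes the mean log-map
        assert np.abs(tv.mean(axis=0)).max() < 1e-6

    def test_noise_free_session_fully_decoded(self, separable_session):
        from vsabci.evaluate import blockwise_cv
        from vsabci.preprocess import standard_chain

        eps = standard_chain(separable_session)
        cv = blockwise_cv(eps, XdawnTangentLDA, n_boot=500)
        assert cv.estimate.point == 1.0
        assert cv.estimate.ci_low == 1.0


class TestWCBLE:
    def test_zero_width_window_equals_tlda(self, covert_epochs):
        w = WCBLE(search_window_ms=(0.0, 0.0)).fit_epochs(covert_epochs)
        t = ToeplitzLDA().fit_epochs(covert_epochs)
        np.testing.assert_allclose(
            w.score_epochs(covert_epochs), t.score_epochs(covert_epochs), atol=1e-12
        )

    def test_plain_max_dominates_nominal_score(self, covert_epochs):
        """Without smoothing/prior the max over lags includes the nominal lag."""
        w = WCBLE(smooth_lags_ms=0.0, test_prior_sd_ms=None).fit_epochs(covert_epochs)
        shifts = np.zeros(len(covert_epochs), dtype=int)
        nominal = w.base_.decision_function(w._cut(covert_epochs.data, shifts))
        assert (w.score_epochs(covert_epochs) >= nominal - 1e-12).all()

    def test_known_shift_recovered(self, covert_epochs):
        """An epoch equal to the target template shifted +80 ms reports a
        latency within +/-10 ms of +80."""
        w = WCBLE().fit_epochs(covert_epochs)
        tmpl = covert_epochs.data[covert_epochs.labels].mean(axis=0)
        shifted = np.roll(tmpl, 80, axis=1)[None]
        _, lat = w.transform_latencies(shifted)
        assert abs(lat[0] - 80.0) <= 10.0

    def test_zero_jitter_training_latencies_near_zero(self):
        from vsabci.paradigm import covert_profile_pair, simulate_session, NoiseSpec
        from vsabci.preprocess import standard_chain

        s = simulate_session(
            profiles=covert_profile_pair(0.0), noise=NoiseSpec(rms_uv=0.5),
            seed=21, conditions=("covert",),
        )
        eps = standard_chain(s)
        w = WCBLE(n_iter=1).fit_epochs(eps)
        assert np.abs(w.train_latencies_ms_).mean() < 10.0

    def test_search_window_exceeding_slack_rejected(self, covert_epochs):
        with pytest.raises(DomainError, match="search window"):
            WCBLE(search_window_ms=(-300.0, 300.0)).fit_epochs(covert_epochs)

    def test_all_zero_epoch_scores_intercept(self, covert_epochs):
        w = WCBLE(smooth_lags_ms=0.0, test_prior_sd_ms=None).fit_epochs(covert_epochs)
        zero = np.zeros((1,) + covert_epochs.data.shape[1:])
        assert np.isclose(w.decision_function(zero)[0], w.base_.intercept_)

    def test_deterministic_given_fitted_state(self, covert_epochs):
        w = WCBLE().fit_epochs(covert_epochs)
        s1 = w.score_epochs(covert_epochs)
        s2 = w.score_epochs(covert_epochs)
        np.testing.assert_array_equal(s1, s2)


class TestSerialization:
    def test_tlda_roundtrip(self, covert_epochs, tmp_path):
        m = ToeplitzLDA().fit_epochs(covert_epochs)
        save_decoder(m, tmp_path / "m")
        loaded = load_decoder(tmp_path / "m")
        x, _ = crop_and_decimate(covert_epochs)
        np.testing.assert_allclose(
            loaded.decision_function(x), m.decision_function(x), rtol=1e-12
        )

    def test_wcble_roundtrip(self, covert_epochs, tmp_path):
        m = WCBLE().fit_epochs(covert_epochs)
        save_decoder(m, tmp_path / "m")
        loaded = load_decoder(tmp_path / "m")
        np.testing.assert_allclose(
            loaded.score_epochs(covert_epochs), m.score_epochs(covert_epochs),
            rtol=1e-12,
        )


def test_make_decoder_names():
    assert isinstance(make_decoder("tlda"), ToeplitzLDA)
    assert isinstance(make_decoder("xdawn_ts"), XdawnTangentLDA)
    assert isinstance(make_decoder("wcble"), WCBLE)
    with pytest.raises(DomainError, match="valid options"):
        make_decoder("tldaa")
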