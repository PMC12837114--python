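"""ERP decoders: block-Toeplitz LDA, xDAWN-covariance tangent-space LDA, WCBLE.

All three decoders produce a per-epoch scalar decision score (higher = more
target-like) from spatiotemporal ERP features.

* :class:`ToeplitzLDA` (tLDA) is a binary shrinkage LDA whose pooled
  spatiotemporal covariance is constrained to block-Toeplitz structure over
  time lags: the channels-x-channels cross-covariance between two feature
  time points is assumed to depend only on their lag difference, which makes
  the d = channels x lags covariance estimable from typical calibration data.

* :class:`XdawnTangentLDA` applies xDAWN spatial filtering, augments each
  filtered epoch with the filtered class-mean prototypes, takes the epoch
  covariance of the augmented matrix, projects all covariances to the
  tangent space at their affine-invariant Riemannian mean and classifies the
  tangent vectors with shrinkage LDA.

* :class:`WCBLE` (classifier-based latency estimation with Woody iterations)
  wraps tLDA in an iterative alignment scheme for latency-jittered ERPs:
  slide the trained classifier over a wide epoch, take each target epoch's
  latency at the score maximum, realign, retrain; at test time the score of
  an epoch is the maximum sliding score over the latency search window.

Decoders expose the sklearn idiom ``fit(X, y)`` / ``decision_function(X)``
on 3-D feature arrays, plus ``fit_epochs`` / ``score_epochs`` convenience
wrappers operating on :class:`~vsabci.preprocess.EpochSet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh
from scipy.ndimage import gaussian_filter1d
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from vsabci.errors import DomainError
from vsabci.preprocess import EpochSet


@dataclass(frozen=True)
class FeatureLayout:
    """Shape contract of decoder inputs: channels and kept time samples."""

    n_channels: int
    n_times: int
    window_ms: tuple[float, float]
    decim: int

    def check(self, x: np.ndarray) -> None:
        if x.ndim != 3 or x.shape[1] != self.n_channels or x.shape[2] != self.n_times:
            raise DomainError(
                f"feature shape {x.shape} does not match trained layout "
                f"(n, {self.n_channels}, {self.n_times})"
            )


def crop_and_decimate(
    epochs: EpochSet,
    window_ms: tuple[float, float] = (0.0, 800.0),
    decim: int = 20,
) -> tuple[np.ndarray, FeatureLayout]:
    """Crop epochs to ``window_ms`` (half-open) and decimate by stride.

    The preprocessing band-pass (16 Hz) already limits bandwidth, so plain
    stride decimation is alias-free for the default factor (1000/20 = 50 Hz).
    Returns (n_epochs, n_channels, n_kept) features and the layout.
    """
    lo_s, hi_s = window_ms[0] / 1000.0, window_ms[1] / 1000.0
    eps = 0.5 / epochs.sfreq
    if lo_s < epochs.tmin - eps or hi_s > epochs.tmax + eps:
        raise DomainError(
            f"window {window_ms} ms outside epoch span "
            f"[{epochs.tmin * 1000:g}, {epochs.tmax * 1000:g}] ms"
        )
    start = int(round((lo_s - epochs.tmin) * epochs.sfreq))
    stop = int(round((hi_s - epochs.tmin) * epochs.sfreq))
    x = epochs.data[:, :, start:stop:decim]
    layout = FeatureLayout(
        n_channels=x.shape[1], n_times=x.shape[2], window_ms=tuple(window_ms), decim=decim
    )
    return np.ascontiguousarray(x), layout


def _flatten_time_major(x: np.ndarray) -> np.ndarray:
    """(n, ch, k) -> (n, k*ch): lag-major blocks of channels."""
    return x.transpose(0, 2, 1).reshape(x.shape[0], -1)


def _block_toeplitz_average(s: np.ndarray, n_ch: int, n_lags: int) -> np.ndarray:
    """Average the (ch x ch) blocks of equal lag difference of a covariance."""
    b = s.reshape(n_lags, n_ch, n_lags, n_ch)
    out = np.empty_like(b)
    for delta in range(n_lags):
        idx = np.arange(n_lags - delta)
        avg = b[idx + delta, :, idx, :].mean(axis=0)
        out[idx + delta, :, idx, :] = avg
        if delta:
            out[idx, :, idx + delta, :] = avg.T
    res = out.reshape(n_lags * n_ch, n_lags * n_ch)
    return (res + res.T) / 2.0


class ToeplitzLDA:
    """Binary shrinkage LDA with a block-Toeplitz spatiotemporal covariance.

    Parameters
    ----------
    shrinkage : 'auto' or float in [0, 1]
        'auto' uses the Ledoit-Wolf analytic shrinkage intensity computed on
        the class-centered training data; a float is used as-is. The shrunk
        covariance is (1 - g) * Sigma_toeplitz + g * (tr(Sigma)/d) * I.
    """

    def __init__(self, shrinkage: str | float = "auto"):
        self.shrinkage = shrinkage

    def fit(self, x: np.ndarray, y: np.ndarray) -> "ToeplitzLDA":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y).astype(bool)
        if x.ndim != 3:
            raise DomainError("expected features of shape (n, channels, times)")
        if y.all() or not y.any():
            raise DomainError("both classes must be present")
        if min(y.sum(), (~y).sum()) < 2:
            raise DomainError("need at least 2 epochs per class")
        n, n_ch, n_lags = x.shape
        xf = _flatten_time_major(x)
        mu_t = xf[y].mean(axis=0)
        mu_nt = xf[~y].mean(axis=0)
        centered = xf.copy()
        centered[y] -= mu_t
        centered[~y] -= mu_nt
        d = xf.shape[1]
        s = centered.T @ centered / n  # ML divisor: invariant under epoch duplication
        s_toep = _block_toeplitz_average(s, n_ch, n_lags)
        gamma = (
            float(ledoit_wolf_shrinkage(centered, assume_centered=True))
            if self.shrinkage == "auto"
            else float(self.shrinkage)
        )
        nu = np.trace(s_toep) / d
        sigma = (1.0 - gamma) * s_toep + gamma * nu * np.eye(d)
        w = np.linalg.solve(sigma, mu_t - mu_nt)
        self.layout_ = FeatureLayout(n_ch, n_lags, (np.nan, np.nan), 1)
        self.coef_ = w
        self.intercept_ = float(-w @ (mu_t + mu_nt) / 2.0)
        self.means_ = (mu_t, mu_nt)
        self.shrinkage_ = gamma
        self.cov_ = sigma
        return self

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        self._check_fitted()
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != self.layout_.n_channels or x.shape[2] != self.layout_.n_times:
            raise DomainError(
                f"feature shape {x.shape} does not match trained layout "
                f"(n, {self.layout_.n_channels}, {self.layout_.n_times})"
            )
        return _flatten_time_major(x) @ self.coef_ + self.intercept_

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise DomainError("decoder is not fitted")

    # -- EpochSet convenience -------------------------------------------------

    window_ms: tuple[float, float] = (0.0, 800.0)
    decim: int = 20

    def fit_epochs(self, epochs: EpochSet) -> "ToeplitzLDA":
        x, layout = crop_and_decimate(epochs, self.window_ms, self.decim)
        self.fit(x, epochs.labels)
        self.layout_ = layout
        return self

    def score_epochs(self, epochs: EpochSet) -> np.ndarray:
        x, _ = crop_and_decimate(epochs, self.window_ms, self.decim)
        return self.decision_function(x)


# ---------------------------------------------------------------------------
# xDAWN + tangent space
# ---------------------------------------------------------------------------


def _matrix_power_sym(c: np.ndarray, p: float) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 1e-300, None)
    return (v * w**p) @ v.T


def _logm_sym(c: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(c)
    w = np.clip(w, 1e-300, None)
    return (v * np.log(w)) @ v.T


def riemannian_mean(
    covs: np.ndarray, tol: float = 1e-8, max_iter: int = 50
) -> np.ndarray:
    """Affine-invariant (geometric) mean of SPD matrices, fixed-point iteration."""
    g = covs.mean(axis=0)
    for _ in range(max_iter):
        g_isqrt = _matrix_power_sym(g, -0.5)
        g_sqrt = _matrix_power_sym(g, 0.5)
        logs = np.stack([_logm_sym(g_isqrt @ c @ g_isqrt) for c in covs])
        step = logs.mean(axis=0)
        norm = np.linalg.norm(step, "fro")
        w, v = np.linalg.eigh(step)
        expm = (v * np.exp(w)) @ v.T
        g = g_sqrt @ expm @ g_sqrt
        g = (g + g.T) / 2.0
        if norm < tol:
            break
    return g


def tangent_vectors(covs: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Project SPD matrices to the tangent space at ``ref``.

    Returns vectors of length d(d+1)/2 (upper triangle, off-diagonals
    scaled by sqrt(2) so the Euclidean norm matches the AIRM distance).
    """
    d = ref.shape[0]
    ref_isqrt = _matrix_power_sym(ref, -0.5)
    iu = np.triu_indices(d)
    scale = np.where(iu[0] == iu[1], 1.0, np.sqrt(2.0))
    out = np.empty((len(covs), len(iu[0])))
    for i, c in enumerate(covs):
        s = _logm_sym(ref_isqrt @ c @ ref_isqrt)
        out[i] = s[iu] * scale
    return out


class XdawnTangentLDA:
    """xDAWN-covariance + tangent-space + shrinkage-LDA decoder.

    ``n_filters`` xDAWN spatial filters are obtained from the generalized
    eigendecomposition of (target-evoked covariance, noise covariance). Each
    epoch is augmented with the filtered target and non-target prototypes
    (d = 3 * n_filters rows), its covariance is regularized by eigenvalue
    flooring at ``eig_floor`` x trace, and classified in the tangent space at
    the affine-invariant mean of the training covariances.
    """

    def __init__(
        self,
        n_filters: int = 4,
        eig_floor: float = 1e-10,
        mean_tol: float = 1e-8,
        mean_max_iter: int = 50,
    ):
        self.n_filters = n_filters
        self.eig_floor = eig_floor
        self.mean_tol = mean_tol
        self.mean_max_iter = mean_max_iter

    # EpochSet defaults
    window_ms: tuple[float, float] = (0.0, 800.0)
    decim: int = 20

    def fit(self, x: np.ndarray, y: np.ndarray) -> "XdawnTangentLDA":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y).astype(bool)
        if y.all() or not y.any():
            raise DomainError("both classes must be present")
        n, n_ch, k = x.shape
        p_t = x[y].mean(axis=0)
        p_nt = x[~y].mean(axis=0)
        resid = np.concatenate([xi for xi in x], axis=1)
        c_noise = resid @ resid.T / resid.shape[1]
        c_noise += 1e-9 * np.trace(c_noise) / n_ch * np.eye(n_ch)
        c_sig = p_t @ p_t.T / k
        try:
            w, v = eigh(c_sig, c_noise)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise DomainError(
                "generalized eigendecomposition failed; covariance is rank "
                "deficient — increase regularization or epochs"
            ) from exc
        filters = v[:, ::-1][:, : self.n_filters].T  # (n_filters, n_ch)
        self.filters_ = filters
        self.prototypes_ = (filters @ p_t, filters @ p_nt)
        covs = self._augmented_covs(x)
        self.ref_mean_ = riemannian_mean(covs, self.mean_tol, self.mean_max_iter)
        tv = tangent_vectors(covs, self.ref_mean_)
        self.lda_ = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        self.lda_.fit(tv, y.astype(int))
        self.layout_ = FeatureLayout(n_ch, k, (np.nan, np.nan), 1)
        return self

    def _augmented_covs(self, x: np.ndarray) -> np.ndarray:
        p_t, p_nt = self.prototypes_
        k = x.shape[2]
        covs = []
        for xi in x:
            z = np.vstack([p_t, p_nt, self.filters_ @ xi])
            c = z @ z.T / (k - 1)
            w, v = np.linalg.eigh(c)
            floor = self.eig_floor * max(np.trace(c), 1e-300)
            w = np.maximum(w, floor)
            covs.append((v * w) @ v.T)
        return np.stack(covs)

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        if not hasattr(self, "filters_"):
            raise DomainError("decoder is not fitted")
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 3 or x.shape[1] != self.layout_.n_channels or x.shape[2] != self.layout_.n_times:
            raise DomainError(f"feature shape {x.shape} does not match trained layout")
        tv = tangent_vectors(self._augmented_covs(x), self.ref_mean_)
        return self.lda_.decision_function(tv)

    def fit_epochs(self, epochs: EpochSet) -> "XdawnTangentLDA":
        x, layout = crop_and_decimate(epochs, self.window_ms, self.decim)
        self.fit(x, epochs.labels)
        self.layout_ = layout
        return self

    def score_epochs(self, epochs: EpochSet) -> np.ndarray:
        x, _ = crop_and_decimate(epochs, self.window_ms, self.decim)
        return self.decision_function(x)


# ---------------------------------------------------------------------------
# WCBLE
# ---------------------------------------------------------------------------


class WCBLE:
    """Woody-style classifier-based latency estimation around tLDA.

    Operates on wide epochs (default -100..900 ms). Iteration 0 fits tLDA on
    the nominal 0..800 ms window. Each Woody iteration slides the classifier
    template over every *target* training epoch, estimates its latency at
    the maximum classification score inside ``search_window_ms``, re-cuts the
    target epochs at their aligned windows (non-targets stay at nominal
    alignment — they carry no P3 to align) and refits. Iterations stop after
    ``n_iter`` or when the mean absolute latency change drops below
    ``tol_ms``. At test time every epoch is scored by the maximum sliding
    score; argmax ties resolve to the earliest latency.

    Two regularizations stabilize peak picking at single-trial SNR, where
    the raw score-vs-lag curve is noise-dominated:

    - ``smooth_lags_ms``: the score curve is smoothed over lags with a
      Gaussian kernel of this SD before peak picking (both when estimating
      training latencies and at test time). 0 disables.
    - ``test_prior_sd_ms``: at test time, a Gaussian log-prior penalty on
      the shift, ``- scale * tau^2 / (2 * sd^2)`` with ``scale`` the SD of
      the nominal-lag training scores, discounts large latency excursions
      that are not strongly supported by the data. Training-time latency
      estimation stays unpenalized (``train_prior_sd_ms=None``) so that
      alignment is not biased toward the nominal latency; a value can be set
      to shrink training estimates too. The penalty vanishes at the nominal
      lag, so a zero-width search window reduces WCBLE exactly to tLDA.

    Setting ``smooth_lags_ms=0`` and ``test_prior_sd_ms=None`` yields the
    plain convolve-and-maximize rule.
    """

    def __init__(
        self,
        search_window_ms: tuple[float, float] = (-100.0, 100.0),
        n_iter: int = 3,
        tol_ms: float = 5.0,
        step_ms: float = 5.0,
        window_ms: tuple[float, float] = (0.0, 800.0),
        decim: int = 20,
        shrinkage: str | float = "auto",
        smooth_lags_ms: float = 30.0,
        train_prior_sd_ms: float | None = None,
        test_prior_sd_ms: float | None = 150.0,
    ):
        if n_iter < 1:
            raise DomainError("n_iter must be >= 1")
        if search_window_ms[0] > search_window_ms[1]:
            raise DomainError("invalid search window")
        self.search_window_ms = search_window_ms
        self.n_iter = n_iter
        self.tol_ms = tol_ms
        self.step_ms = step_ms
        self.window_ms = window_ms
        self.decim = decim
        self.shrinkage = shrinkage
        self.smooth_lags_ms = smooth_lags_ms
        self.train_prior_sd_ms = train_prior_sd_ms
        self.test_prior_sd_ms = test_prior_sd_ms

    # -- index bookkeeping ----------------------------------------------------

    def _setup_indices(self, n_samples: int, sfreq: float, tmin: float) -> None:
        start = int(round((self.window_ms[0] / 1000.0 - tmin) * sfreq))
        n_keep = int(
            round((self.window_ms[1] - self.window_ms[0]) / 1000.0 * sfreq / self.decim)
        )
        base_idx = start + np.arange(n_keep) * self.decim
        lo, hi = self.search_window_ms
        if hi == lo:
            lags_ms = np.array([lo])
        else:
            lags_ms = np.arange(lo, hi + 1e-9, self.step_ms)
        lags = np.round(lags_ms * sfreq / 1000.0).astype(int)
        if base_idx[0] + lags.min() < 0 or base_idx[-1] + lags.max() > n_samples - 1:
            raise DomainError(
                f"search window {self.search_window_ms} ms does not fit inside the "
                f"wide epoch (samples 0..{n_samples - 1})"
            )
        self._base_idx = base_idx
        self._lags = lags
        self._lags_ms = lags / sfreq * 1000.0
        self._sfreq = sfreq

    def _sliding_scores(
        self,
        x: np.ndarray,
        model: ToeplitzLDA,
        prior_sd_ms: float | None,
    ) -> np.ndarray:
        """(n, L) classification score at every candidate lag.

        Smoothing over lags (``smooth_lags_ms``) is applied first; with an
        active ``prior_sd_ms``, the Gaussian log-prior penalty (scaled by
        the training score SD) is then subtracted, making the argmax a MAP
        latency estimate rather than a pure ML one.
        """
        idx = self._base_idx[None, :] + self._lags[:, None]  # (L, k)
        gathered = x[:, :, idx]  # (n, ch, L, k)
        w = model.coef_.reshape(len(self._base_idx), x.shape[1]).T  # (ch, k)
        scores = np.einsum("nclk,ck->nl", gathered, w) + model.intercept_
        if scores.shape[1] > 1:
            if self.smooth_lags_ms > 0:
                # denoise the score-vs-lag curve before peak picking
                scores = gaussian_filter1d(
                    scores, sigma=self.smooth_lags_ms / self.step_ms, axis=1,
                    mode="nearest",
                )
            if prior_sd_ms is not None:
                penalty = (
                    self._score_scale_ * self._lags_ms**2 / (2.0 * prior_sd_ms**2)
                )
                scores = scores - penalty[None, :]
        return scores

    def _cut(self, x: np.ndarray, shifts: np.ndarray) -> np.ndarray:
        """Re-cut epochs at per-epoch shifted windows (shifts in samples)."""
        return np.stack([xi[:, self._base_idx + s] for xi, s in zip(x, shifts)])

    def fit(
        self, x: np.ndarray, y: np.ndarray, sfreq: float = 1000.0, tmin: float = -0.1
    ) -> "WCBLE":
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y).astype(bool)
        if x.ndim != 3:
            raise DomainError("expected wide epochs of shape (n, channels, samples)")
        self._setup_indices(x.shape[2], sfreq, tmin)
        self.wide_layout_ = FeatureLayout(x.shape[1], x.shape[2], self.search_window_ms, 1)

        shifts = np.zeros(x.shape[0], dtype=int)
        cut0 = self._cut(x, shifts)
        base = ToeplitzLDA(self.shrinkage).fit(cut0, y)
        self._score_scale_ = float(np.std(base.decision_function(cut0)))
        self.convergence_: list[float] = []
        tgt = np.flatnonzero(y)
        latencies_ms = np.zeros(len(tgt))
        if len(self._lags) > 1:
            for _ in range(self.n_iter):
                scores = self._sliding_scores(x[tgt], base, self.train_prior_sd_ms)
                best = np.argmax(scores, axis=1)  # first max = earliest lag
                new_ms = self._lags_ms[best]
                delta = float(np.mean(np.abs(new_ms - latencies_ms)))
                self.convergence_.append(delta)
                latencies_ms = new_ms
                shifts[tgt] = self._lags[best]
                cut = self._cut(x, shifts)
                base = ToeplitzLDA(self.shrinkage).fit(cut, y)
                self._score_scale_ = float(np.std(base.decision_function(cut)))
                if delta < self.tol_ms:
                    break
        self.base_ = base
        self.n_iter_done_ = len(self.convergence_)
        self.train_latencies_ms_ = latencies_ms
        return self

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        if not hasattr(self, "base_"):
            raise DomainError("decoder is not fitted")
        x = np.asarray(x, dtype=np.float64)
        if (
            x.ndim != 3
            or x.shape[1] != self.wide_layout_.n_channels
            or x.shape[2] != self.wide_layout_.n_times
        ):
            raise DomainError(f"wide-epoch shape {x.shape} does not match trained layout")
        return x

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        return self.transform_latencies(x)[0]

    def transform_latencies(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-epoch (max sliding score, argmax latency in ms)."""
        x = self._check_input(x)
        scores = self._sliding_scores(x, self.base_, self.test_prior_sd_ms)
        best = np.argmax(scores, axis=1)
        return scores[np.arange(len(x)), best], self._lags_ms[best]

    def fit_epochs(self, epochs: EpochSet) -> "WCBLE":
        return self.fit(epochs.data, epochs.labels, sfreq=epochs.sfreq, tmin=epochs.tmin)

    def score_epochs(self, epochs: EpochSet) -> np.ndarray:
        return self.decision_function(epochs.data)


# ---------------------------------------------------------------------------
# registry + serialization
# ---------------------------------------------------------------------------

DECODERS = {
    "tlda": ToeplitzLDA,
    "xdawn_ts": XdawnTangentLDA,
    "wcble": WCBLE,
}


def make_decoder(name: str, **kwargs):
    """Instantiate a decoder by CLI name ('tlda', 'xdawn_ts', 'wcble')."""
    try:
        cls = DECODERS[name]
    except KeyError:
        raise DomainError(
            f"unknown decoder {name!r}; valid options: {sorted(DECODERS)}"
        ) from None
    return cls(**kwargs)


_FORMAT_VERSION = 1


def save_decoder(model, path: str | Path) -> None:
    """Serialize a fitted tLDA or WCBLE model to <path>/model.json + weights.npz."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(model, ToeplitzLDA):
        kind, base = "tlda", model
        extra: dict = {}
        arrays = {}
    elif isinstance(model, WCBLE):
        kind, base = "wcble", model.base_
        extra = {
            "search_window_ms": list(model.search_window_ms),
            "n_iter": model.n_iter,
            "tol_ms": model.tol_ms,
            "step_ms": model.step_ms,
            "window_ms": list(model.window_ms),
            "decim": model.decim,
            "wide_n_channels": model.wide_layout_.n_channels,
            "wide_n_times": model.wide_layout_.n_times,
            "sfreq": model._sfreq,
            "smooth_lags_ms": model.smooth_lags_ms,
            "train_prior_sd_ms": model.train_prior_sd_ms,
            "test_prior_sd_ms": model.test_prior_sd_ms,
            "score_scale": model._score_scale_,
        }
        arrays = {"base_idx": model._base_idx, "lags": model._lags}
    else:
        raise DomainError(f"cannot serialize decoder of type {type(model).__name__}")
    base._check_fitted()
    meta = {
        "format_version": _FORMAT_VERSION,
        "kind": kind,
        "intercept": base.intercept_,
        "shrinkage": base.shrinkage_,
        "n_channels": base.layout_.n_channels,
        "n_times": base.layout_.n_times,
        **extra,
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "weights.npz", coef=base.coef_, mu_t=base.means_[0],
             mu_nt=base.means_[1], **arrays)


def load_decoder(path: str | Path):
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise DomainError(f"unsupported model format version {meta.get('format_version')}")
    arrays = np.load(path / "weights.npz")
    base = ToeplitzLDA(meta["shrinkage"])
    base.coef_ = arrays["coef"]
    base.intercept_ = float(meta["intercept"])
    base.means_ = (arrays["mu_t"], arrays["mu_nt"])
    base.shrinkage_ = meta["shrinkage"]
    base.layout_ = FeatureLayout(meta["n_channels"], meta["n_times"], (np.nan, np.nan), 1)
    if meta["kind"] == "tlda":
        return base
    model = WCBLE(
        search_window_ms=tuple(meta["search_window_ms"]),
        n_iter=meta["n_iter"], tol_ms=meta["tol_ms"], step_ms=meta["step_ms"],
        window_ms=tuple(meta["window_ms"]), decim=meta["decim"],
        smooth_lags_ms=meta.get("smooth_lags_ms", 0.0),
        train_prior_sd_ms=meta.get("train_prior_sd_ms"),
        test_prior_sd_ms=meta.get("test_prior_sd_ms"),
    )
    model._score_scale_ = float(meta.get("score_scale", 1.0))
    model.base_ = base
    model._base_idx = arrays["base_idx"]
    model._lags = arrays["lags"]
    model._sfreq = meta["sfreq"]
    model._lags_ms = model._lags / meta["sfreq"] * 1000.0
    model.wide_layout_ = FeatureLayout(
        meta["wide_n_channels"], meta["wide_n_times"], tuple(meta["search_window_ms"]), 1
    )
    model.convergence_ = []
    model.n_iter_done_ = 0
    return model
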