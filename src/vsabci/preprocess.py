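"""EEG preprocessing: band-pass, bad-channel detection, re-referencing, epoching.

The chain mirrors standard ERP practice for oddball decoding: zero-phase
band-pass 0.5-16 Hz, RANSAC-style bad-channel flagging, re-reference to the
mastoid average (TP9/TP10), stimulus-locked epochs from -0.1 to 0.9 s with no
baseline correction for decoding, and wider baseline-corrected epochs for ERP
visualization. An optional EOG linear-regression stage removes ocular
artifacts; bad channels are excluded from decoding rather than interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from vsabci.errors import DomainError
from vsabci.paradigm import SimulatedSession

logger = logging.getLogger(__name__)


@dataclass
class Recording:
    """Continuous multichannel recording (channels x samples, microvolts)."""

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    ch_types: list[str]
    bads: list[str] = field(default_factory=list)

    @classmethod
    def from_session(cls, session: SimulatedSession) -> "Recording":
        return cls(
            data=session.eeg.copy(),
            sfreq=session.sfreq,
            ch_names=list(session.ch_names),
            ch_types=list(session.ch_types),
        )

    def picks(self, ch_type: str = "eeg", exclude_bads: bool = False) -> np.ndarray:
        idx = [
            i
            for i, (n, t) in enumerate(zip(self.ch_names, self.ch_types))
            if t == ch_type and not (exclude_bads and n in self.bads)
        ]
        return np.asarray(idx, dtype=int)

    def copy(self) -> "Recording":
        return replace(
            self,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            ch_types=list(self.ch_types),
            bads=list(self.bads),
        )


@dataclass
class ChannelQualityReport:
    """RANSAC bad-channel flags with per-channel predictability scores."""

    ch_names: list[str]
    flags: dict[str, bool]          # True = bad
    scores: dict[str, float]        # median cross-window correlation
    params: dict

    @property
    def bads(self) -> list[str]:
        return [ch for ch in self.ch_names if self.flags[ch]]

    def to_json_dict(self) -> dict:
        return {
            "bads": self.bads,
            "flags": self.flags,
            "scores": self.scores,
            "params": self.params,
        }


@dataclass
class EpochSet:
    """Stimulus-locked epochs with paradigm bookkeeping.

    ``data`` is (n_epochs, n_channels, n_samples) over the half-open window
    [tmin, tmax); ``info`` carries one row per epoch (onset_ms, block_id,
    condition, cued_target, stimulus_target, is_target, rep_index) where
    ``rep_index`` is the 0-based intensification order of that stimulus
    within its block.
    """

    data: np.ndarray
    tmin: float
    tmax: float
    sfreq: float
    ch_names: list[str]
    info: pd.DataFrame
    baseline_corrected: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        expected = int(round((self.tmax - self.tmin) * self.sfreq))
        if self.data.shape[2] != expected:
            raise DomainError(
                f"epoch length {self.data.shape[2]} != round((tmax-tmin)*sfreq) = {expected}"
            )
        if len(self.info) != self.data.shape[0]:
            raise DomainError("info rows do not match number of epochs")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.sfreq

    @property
    def labels(self) -> np.ndarray:
        return self.info["is_target"].to_numpy(dtype=bool)

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            data=self.data[idx],
            info=self.info.iloc[idx].reset_index(drop=True),
        )

    def pick_channels(self, names: Sequence[str]) -> "EpochSet":
        order = [self.ch_names.index(n) for n in names]
        return replace(self, data=self.data[:, order, :], ch_names=list(names))

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float32))
            f.attrs.update(
                tmin=self.tmin, tmax=self.tmax, sfreq=self.sfreq,
                baseline_corrected=self.baseline_corrected, n_dropped=self.n_dropped,
            )
            f.attrs["ch_names"] = [n.encode() for n in self.ch_names]
            g = f.create_group("info")
            for col in self.info.columns:
                vals = self.info[col].to_numpy()
                if vals.dtype == object:
                    vals = vals.astype("S")
                g.create_dataset(col, data=vals)
            g.attrs["columns"] = [c.encode() for c in self.info.columns]

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()].astype(np.float64)
            def _s(v):
                return v.decode() if isinstance(v, bytes) else str(v)

            cols = [_s(c) for c in f["info"].attrs["columns"]]
            info = {}
            for col in cols:
                v = f["info"][col][()]
                if v.dtype.kind == "S":
                    v = np.char.decode(v)
                info[col] = v
            return cls(
                data=data,
                tmin=float(f.attrs["tmin"]),
                tmax=float(f.attrs["tmax"]),
                sfreq=float(f.attrs["sfreq"]),
                ch_names=[_s(n) for n in f.attrs["ch_names"]],
                info=pd.DataFrame(info),
                baseline_corrected=bool(f.attrs["baseline_corrected"]),
                n_dropped=int(f.attrs["n_dropped"]),
            )


def bandpass(rec: Recording, lo: float = 0.5, hi: float = 16.0, order: int = 4) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass.

    Applied to all channels; sample count unchanged.
    """
    nyq = rec.sfreq / 2.0
    if hi >= nyq:
        raise DomainError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    if not 0 < lo < hi:
        raise DomainError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    sos = butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    out = rec.copy()
    out.data = sosfiltfilt(sos, rec.data, axis=1)
    return out


def detect_bad_channels(
    rec: Recording,
    n_resamples: int = 50,
    subset_frac: float = 0.25,
    corr_threshold: float = 0.75,
    bad_fraction: float = 0.4,
    window_s: float = 5.0,
    seed: int = 0,
    max_eval_sfreq: float = 250.0,
) -> ChannelQualityReport:
    """RANSAC-style bad-channel detection.

    In sliding windows, each EEG channel is predicted by least-squares
    spatial regression from random subsets of the other channels; the median
    correlation between prediction and signal over ``n_resamples`` subsets is
    the window score. A channel is flagged bad when its score falls below
    ``corr_threshold`` in more than ``bad_fraction`` of windows. The signal
    is decimated to ``max_eval_sfreq`` for the regression only.
    """
    eeg_idx = rec.picks("eeg")
    if len(eeg_idx) < 8:
        raise DomainError("need at least 8 EEG channels")
    subset_size = max(2, int(round(subset_frac * len(eeg_idx))))
    if subset_size >= len(eeg_idx):
        raise DomainError("subset_size must be smaller than the channel count")
    rng = np.random.default_rng(seed)

    step = max(1, int(rec.sfreq // max_eval_sfreq))
    x = rec.data[eeg_idx, ::step]
    wlen = max(8, int(round(window_s * rec.sfreq / step)))
    n_win = max(1, x.shape[1] // wlen)
    n_ch = len(eeg_idx)

    below = np.zeros(n_ch, dtype=int)
    med_scores = np.zeros((n_ch, n_win))
    for w in range(n_win):
        seg = x[:, w * wlen : (w + 1) * wlen]
        seg = seg - seg.mean(axis=1, keepdims=True)
        sd = seg.std(axis=1)
        for ci in range(n_ch):
            others = np.delete(np.arange(n_ch), ci)
            corrs = np.empty(n_resamples)
            for r in range(n_resamples):
                sub = rng.choice(others, size=subset_size, replace=False)
                a = seg[sub].T
                beta, *_ = np.linalg.lstsq(a, seg[ci], rcond=None)
                pred = a @ beta
                ps = pred.std()
                if sd[ci] == 0 or ps == 0:
                    corrs[r] = 0.0
                else:
                    corrs[r] = float(np.dot(pred, seg[ci]) / (len(pred) * ps * sd[ci]))
            med = float(np.median(corrs))
            med_scores[ci, w] = med
            if med < corr_threshold:
                below[ci] += 1

    flags = below / n_win > bad_fraction
    names = [rec.ch_names[i] for i in eeg_idx]
    return ChannelQualityReport(
        ch_names=names,
        flags={n: bool(f) for n, f in zip(names, flags)},
        scores={n: float(np.median(med_scores[i])) for i, n in enumerate(names)},
        params=dict(
            n_resamples=n_resamples, subset_size=subset_size,
            corr_threshold=corr_threshold, bad_fraction=bad_fraction,
            window_s=window_s, seed=seed,
        ),
    )


def rereference_mastoids(
    rec: Recording, refs: tuple[str, str] = ("TP9", "TP10")
) -> Recording:
    """Re-reference every EEG channel to the average of the mastoids.

    EOG channels are untouched. Idempotent: after one application the
    reference average is identically zero.
    """
    for ref in refs:
        if ref not in rec.ch_names:
            raise DomainError(f"reference channel {ref!r} not in recording")
        if ref in rec.bads:
            raise DomainError(f"reference channel {ref!r} is flagged bad")
    out = rec.copy()
    ref_idx = [rec.ch_names.index(r) for r in refs]
    ref_sig = rec.data[ref_idx].mean(axis=0)
    out.data[rec.picks("eeg")] -= ref_sig
    return out


def regress_eog(rec: Recording) -> Recording:
    """Remove ocular artifacts by least-squares EOG regression.

    Fits each EEG channel on the EOG channels (with intercept) and subtracts
    the fitted ocular contribution. A documented alternative to
    visual-inspection ICA cleaning; off by default in the standard chain.
    """
    eog_idx = rec.picks("eog")
    if len(eog_idx) == 0:
        raise DomainError("no EOG channels in recording")
    out = rec.copy()
    eog = rec.data[eog_idx]
    design = np.vstack([eog, np.ones(eog.shape[1])]).T
    eeg_idx = rec.picks("eeg")
    beta, *_ = np.linalg.lstsq(design, rec.data[eeg_idx].T, rcond=None)
    out.data[eeg_idx] -= (design @ beta).T
    return out


def extract_epochs(
    rec: Recording,
    events: pd.DataFrame,
    tmin: float = -0.1,
    tmax: float = 0.9,
    picks: Sequence[str] | None = None,
) -> EpochSet:
    """Cut stimulus-locked epochs over the half-open window [tmin, tmax).

    One epoch per event whose window fits in the recording; events outside
    are dropped with a logged count. No baseline correction. The label of an
    epoch is ``stimulus_target == cued_target``.
    """
    if picks is None:
        idx = rec.picks("eeg", exclude_bads=True)
        picks = [rec.ch_names[i] for i in idx]
    else:
        idx = np.array([rec.ch_names.index(p) for p in picks])
    n_samp = int(round((tmax - tmin) * rec.sfreq))
    starts = np.round(
        (events["onset_ms"].to_numpy() / 1000.0 + tmin) * rec.sfreq
    ).astype(int)
    ok = (starts >= 0) & (starts + n_samp <= rec.data.shape[1])
    n_dropped = int((~ok).sum())
    if ok.sum() == 0:
        raise DomainError("no event window fits inside the recording")
    if n_dropped:
        logger.info("extract_epochs: dropped %d events outside the recording", n_dropped)

    kept = events.loc[ok].reset_index(drop=True).copy()
    data = np.stack(
        [rec.data[np.ix_(idx, np.arange(s, s + n_samp))] for s in starts[ok]]
    )
    kept["is_target"] = kept["stimulus_target"] == kept["cued_target"]
    kept["rep_index"] = kept.groupby(["block_id", "stimulus_target"]).cumcount()
    kept["epoch_id"] = np.flatnonzero(ok)  # stable identity across selections
    return EpochSet(
        data=data, tmin=tmin, tmax=tmax, sfreq=rec.sfreq,
        ch_names=list(picks), info=kept, n_dropped=n_dropped,
    )


def erp_contrast(epochs: EpochSet, baseline: tuple[float, float] = (-0.2, 0.0)) -> np.ndarray:
    """Target-minus-nontarget grand-average waveform (channels x samples).

    Each epoch is first baseline-corrected by subtracting its mean over the
    ``baseline`` window (intended for visualization epochs, e.g. -0.2..1.0 s).
    """
    labels = epochs.labels
    if labels.all() or not labels.any():
        raise DomainError("both target and non-target epochs are required")
    t = epochs.times
    bmask = (t >= baseline[0]) & (t < baseline[1])
    if not bmask.any():
        raise DomainError("baseline window outside the epoch span")
    corrected = epochs.data - epochs.data[:, :, bmask].mean(axis=2, keepdims=True)
    return corrected[labels].mean(axis=0) - corrected[~labels].mean(axis=0)


def drop_excess_repetitions(epochs: EpochSet, keep: int = 10) -> EpochSet:
    """Keep only the first ``keep`` intensifications of each target per block."""
    if keep < 1:
        raise DomainError("keep must be >= 1")
    return epochs.select((epochs.info["rep_index"] < keep).to_numpy())


def standard_chain(
    session: SimulatedSession,
    lo: float = 0.5,
    hi: float = 16.0,
    tmin: float = -0.1,
    tmax: float = 0.9,
    keep_reps: int | None = 10,
    run_ransac: bool = False,
    eog_regression: bool = False,
) -> EpochSet:
    """Full preprocessing chain from a simulated session to decoding epochs.

    band-pass -> (optional RANSAC bad channels) -> mastoid re-reference ->
    (optional EOG regression) -> epochs [tmin, tmax) -> repetition truncation.
    Bad channels are excluded from the epochs.
    """
    rec = Recording.from_session(session)
    rec = bandpass(rec, lo, hi)
    if run_ransac:
        report = detect_bad_channels(rec)
        rec.bads = report.bads
    rec = rereference_mastoids(rec)
    if eog_regression:
        rec = regress_eog(rec)
    epochs = extract_epochs(rec, session.events, tmin=tmin, tmax=tmax)
    if keep_reps is not None:
        epochs = drop_excess_repetitions(epochs, keep=keep_reps)
    return epochs
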