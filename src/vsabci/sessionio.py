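"""Session persistence: HDF5 continuous EEG + TSV event/gaze/metadata tables.

A session directory contains::

    eeg.h5            continuous EEG (channels x samples, microvolts)
    events.tsv        onset_ms, block_id, condition, cued_target,
                      stimulus_target, is_target
    gaze.tsv          t_ms, lx, ly, rx, ry, l_valid, r_valid
    blocks.tsv        block_id, condition, cued_target, t_start_ms,
                      t_end_ms, gaze_strategy
    ground_truth.tsv  per-event latent state of the simulator

EEG is stored either as float32 or, with ``quantize_bits=16``, as int16
scaled over the recording's physical range — the same quantization an EDF
writer would apply, so round-trip error is bounded by half a quantization
step.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from vsabci.errors import DomainError, SessionFormatError
from vsabci.paradigm import ParadigmConfig, SimulatedSession

EVENT_COLUMNS = [
    "onset_ms", "block_id", "condition", "cued_target", "stimulus_target", "is_target",
]
GAZE_COLUMNS = ["t_ms", "lx", "ly", "rx", "ry", "l_valid", "r_valid"]
BLOCK_COLUMNS = [
    "block_id", "condition", "cued_target", "t_start_ms", "t_end_ms", "gaze_strategy",
]


def write_session(
    session: SimulatedSession,
    path: str | Path,
    quantize_bits: int | None = None,
    force: bool = False,
) -> Path:
    """Write a session directory; returns its path.

    ``quantize_bits=16`` stores EEG as int16 over the physical range
    (EDF-style); ``None`` stores float32.
    """
    path = Path(path)
    if path.exists() and any(path.iterdir()) and not force:
        raise DomainError(f"refusing to overwrite non-empty {path} without force=True")
    path.mkdir(parents=True, exist_ok=True)

    with h5py.File(path / "eeg.h5", "w") as f:
        if quantize_bits is None:
            f.create_dataset("eeg", data=session.eeg.astype(np.float32))
        elif quantize_bits == 16:
            pmin, pmax = float(session.eeg.min()), float(session.eeg.max())
            scale = max(pmax - pmin, 1e-12) / (2**16 - 1)
            ints = np.round((session.eeg - pmin) / scale) - 2**15
            ds = f.create_dataset("eeg", data=ints.astype(np.int16))
            ds.attrs["phys_min"] = pmin
            ds.attrs["scale"] = scale
        else:
            raise DomainError(f"unsupported quantize_bits={quantize_bits}")
        f.attrs["sfreq"] = session.sfreq
        f.attrs["ch_names"] = [n.encode() for n in session.ch_names]
        f.attrs["ch_types"] = [t.encode() for t in session.ch_types]
        f.attrs["seed"] = session.seed

    session.events[EVENT_COLUMNS].to_csv(path / "events.tsv", sep="\t", index=False)
    session.gaze[GAZE_COLUMNS].to_csv(path / "gaze.tsv", sep="\t", index=False)
    session.blocks[BLOCK_COLUMNS].to_csv(path / "blocks.tsv", sep="\t", index=False)
    session.ground_truth.to_csv(path / "ground_truth.tsv", sep="\t", index=False)
    meta = {
        "seed": int(session.seed),
        "sfreq": session.sfreq,
        "n_blocks": int(len(session.blocks)),
        "n_events": int(len(session.events)),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(session.config).items()
        },
    }
    (path / "session.json").write_text(json.dumps(meta, indent=2))
    return path


def _read_tsv(path: Path, required: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV validating rectangular shape; name the offending line."""
    lines = path.read_text().splitlines()
    if not lines:
        raise SessionFormatError(f"{path.name}: empty file")
    n_fields = len(lines[0].split("\t"))
    for i, line in enumerate(lines[1:], start=2):
        k = len(line.split("\t"))
        if k != n_fields:
            raise SessionFormatError(
                f"{path.name}: line {i}: expected {n_fields} fields, got {k}"
            )
    df = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SessionFormatError(f"{path.name}: missing columns {missing}")
        if df[required].isna().any().any():
            bad = int(df[required].isna().any(axis=1).idxmax()) + 2
            raise SessionFormatError(f"{path.name}: line {bad}: missing value")
    return df


def read_session(path: str | Path) -> SimulatedSession:
    """Load a session directory written by :func:`write_session`."""
    path = Path(path)
    eeg_path = path / "eeg.h5"
    if not eeg_path.exists():
        raise SessionFormatError(f"{eeg_path} not found")
    with h5py.File(eeg_path, "r") as f:
        ds = f["eeg"]
        raw = ds[()]
        if raw.dtype == np.int16:
            raw = (raw.astype(np.float64) + 2**15) * ds.attrs["scale"] + ds.attrs["phys_min"]
        else:
            raw = raw.astype(np.float64)
        sfreq = float(f.attrs["sfreq"])
        ch_names = [n.decode() if isinstance(n, bytes) else str(n) for n in f.attrs["ch_names"]]
        ch_types = [t.decode() if isinstance(t, bytes) else str(t) for t in f.attrs["ch_types"]]
        seed = int(f.attrs["seed"])

    events = _read_tsv(path / "events.tsv", EVENT_COLUMNS)
    events["is_target"] = events["is_target"].astype(bool)
    gaze = _read_tsv(path / "gaze.tsv")
    missing = [c for c in GAZE_COLUMNS if c not in gaze.columns]
    if missing:
        raise SessionFormatError(f"gaze.tsv: missing columns {missing}")
    blocks = _read_tsv(path / "blocks.tsv", BLOCK_COLUMNS)
    gt_path = path / "ground_truth.tsv"
    ground_truth = _read_tsv(gt_path) if gt_path.exists() else pd.DataFrame()

    cfg = ParadigmConfig()
    meta_path = path / "session.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        raw_cfg = {
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in meta.get("config", {}).items()
        }
        cfg = ParadigmConfig(**raw_cfg)

    bad = events["onset_ms"] / 1000.0 * sfreq
    if (bad < 0).any() or (bad >= raw.shape[1]).any():
        raise SessionFormatError("events.tsv: onset outside the recording")

    return SimulatedSession(
        eeg=raw, sfreq=sfreq, ch_names=ch_names, ch_types=ch_types,
        events=events, gaze=gaze, blocks=blocks, ground_truth=ground_truth,
        seed=seed, config=cfg,
    )
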