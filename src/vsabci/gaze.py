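"""Eye-tracking post-processing: binocular fusion, stimulus-space mapping,
and per-block gaze-behavior (dwell) summaries.

Fusion follows the rule used for screen-based binocular trackers: when both
eyes are valid the fused sample is their mean, when one eye is missing the
other's value is adopted, and when both are missing the sample stays unset —
gaps are never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from vsabci.errors import DomainError


@dataclass
class FusedGazeTrace:
    """Fused monocular-equivalent gaze trace in screen degrees.

    ``x``/``y`` are NaN exactly where ``source`` is ``"none"``; ``source``
    records which eye(s) produced each sample.
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    source: np.ndarray  # 'both' | 'left' | 'right' | 'none'

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def valid(self) -> np.ndarray:
        return self.source != "none"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_ms": self.t_ms, "x": self.x, "y": self.y, "source": self.source}
        )


def fuse_binocular(gaze: pd.DataFrame) -> FusedGazeTrace:
    """Fuse per-eye gaze samples into one channel per coordinate.

    Expects columns t_ms, lx, ly, rx, ry, l_valid, r_valid. Output length
    equals input length; both-invalid samples are preserved as NaN gaps.
    """
    required = ["t_ms", "lx", "ly", "rx", "ry", "l_valid", "r_valid"]
    missing = [c for c in required if c not in gaze.columns]
    if missing:
        raise DomainError(f"gaze trace missing columns {missing}")
    lv = gaze["l_valid"].to_numpy(dtype=bool)
    rv = gaze["r_valid"].to_numpy(dtype=bool)
    lx, ly = gaze["lx"].to_numpy(float), gaze["ly"].to_numpy(float)
    rx, ry = gaze["rx"].to_numpy(float), gaze["ry"].to_numpy(float)

    n = len(gaze)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    source = np.full(n, "none", dtype=object)

    both = lv & rv
    x[both] = (lx[both] + rx[both]) / 2.0
    y[both] = (ly[both] + ry[both]) / 2.0
    source[both] = "both"

    only_l = lv & ~rv
    x[only_l], y[only_l] = lx[only_l], ly[only_l]
    source[only_l] = "left"

    only_r = rv & ~lv
    x[only_r], y[only_r] = rx[only_r], ry[only_r]
    source[only_r] = "right"

    return FusedGazeTrace(
        t_ms=gaze["t_ms"].to_numpy(float), x=x, y=y, source=np.asarray(source)
    )


def estimate_affine(
    gaze_points: np.ndarray, target_points: np.ndarray
) -> np.ndarray:
    """Least-squares 2x3 affine transform mapping gaze to stimulus space.

    Needs at least 3 non-collinear correspondence pairs (e.g. fixations on
    known calibration targets).
    """
    gaze_points = np.asarray(gaze_points, float)
    target_points = np.asarray(target_points, float)
    if gaze_points.shape[0] < 3:
        raise DomainError("need at least 3 point pairs to estimate an affine map")
    design = np.column_stack([gaze_points, np.ones(len(gaze_points))])
    if np.linalg.matrix_rank(design) < 3:
        raise DomainError("calibration points are collinear")
    coef, *_ = np.linalg.lstsq(design, target_points, rcond=None)
    return coef.T  # (2, 3)


def to_stimulus_space(trace: FusedGazeTrace, affine: np.ndarray) -> FusedGazeTrace:
    """Apply an affine calibration transform; missing samples stay missing."""
    affine = np.asarray(affine, float)
    if affine.shape != (2, 3):
        raise DomainError(f"expected a 2x3 affine matrix, got shape {affine.shape}")
    if abs(np.linalg.det(affine[:, :2])) < 1e-12:
        raise DomainError("affine transform is singular")
    pts = np.column_stack([trace.x, trace.y, np.ones(len(trace))])
    mapped = pts @ affine.T
    return FusedGazeTrace(
        t_ms=trace.t_ms.copy(), x=mapped[:, 0], y=mapped[:, 1],
        source=trace.source.copy(),
    )


def dwell_summary(
    trace: FusedGazeTrace,
    blocks: pd.DataFrame,
    target_positions: np.ndarray,
    radius_deg: float = 3.0,
    overt_threshold: float = 0.5,
    covert_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-block dwell fractions near landmarks and a gaze-strategy label.

    For each block, the fraction of *valid* samples within ``radius_deg`` of
    (a) the cued target, (b) the screen center, (c) any other target, and
    (d) elsewhere. Labels: ``overt-like`` when cued-target dwell exceeds
    ``overt_threshold``, ``covert-like`` when center dwell exceeds
    ``covert_threshold``, ``untracked`` when a block has no valid samples,
    else ``mixed``. The raw fractions are reported alongside the label so
    the classification is auditable.
    """
    rows = []
    for _, blk in blocks.iterrows():
        m = (trace.t_ms >= blk["t_start_ms"]) & (trace.t_ms < blk["t_end_ms"])
        v = m & trace.valid
        n_valid = int(v.sum())
        row = dict(
            block_id=int(blk["block_id"]),
            condition=blk["condition"],
            cued_target=int(blk["cued_target"]),
            n_samples=int(m.sum()),
            n_valid=n_valid,
        )
        if n_valid == 0:
            row.update(
                dwell_cued=np.nan, dwell_center=np.nan, dwell_other=np.nan,
                dwell_elsewhere=np.nan, label="untracked",
            )
            rows.append(row)
            continue
        pts = np.column_stack([trace.x[v], trace.y[v]])
        d_tgt = np.linalg.norm(
            pts[:, None, :] - target_positions[None, :, :], axis=2
        )
        near_any = d_tgt < radius_deg
        cued = int(blk["cued_target"])
        frac_cued = float(near_any[:, cued].mean())
        frac_center = float(
            (np.linalg.norm(pts, axis=1) < radius_deg).mean()
        )
        others = np.delete(np.arange(target_positions.shape[0]), cued)
        frac_other = float(near_any[:, others].any(axis=1).mean())
        frac_else = max(0.0, 1.0 - float(
            (near_any.any(axis=1) | (np.linalg.norm(pts, axis=1) < radius_deg)).mean()
        ))
        if frac_cued > overt_threshold:
            label = "overt-like"
        elif frac_center > covert_threshold:
            label = "covert-like"
        else:
            label = "mixed"
        row.update(
            dwell_cued=frac_cued, dwell_center=frac_center,
            dwell_other=frac_other, dwell_elsewhere=frac_else, label=label,
        )
        rows.append(row)
    return pd.DataFrame(rows)
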