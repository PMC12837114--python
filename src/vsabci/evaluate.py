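"""Target-selection evaluation: block-wise CV, cross-condition transfer,
bootstrap confidence intervals, repetitions-to-threshold.

A *selection* is one BCI decision: six consecutive stimuli covering all six
targets exactly once, decided by the argmax of the per-target decision
scores against the cued target. Accuracy is estimated by 6-fold
cross-validation with folds aligned to stimulation blocks (train on 5
blocks, test on 1), pooled over folds, with 95% percentile-bootstrap
confidence intervals over selections. Cross-condition evaluation trains on
5 blocks of one VSA condition and tests on blocks of another, rotating the
held-out fold index so every block is used symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from vsabci.errors import DomainError
from vsabci.preprocess import EpochSet

logger = logging.getLogger(__name__)

DecoderFactory = Callable[[], object]


@dataclass(frozen=True)
class AccuracyEstimate:
    """Selection-accuracy point estimate with a bootstrap 95% CI."""

    point: float
    ci_low: float
    ci_high: float
    n_selections: int
    n_bootstrap: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0:
            raise DomainError(
                f"require 0 <= low <= point <= high <= 1, got "
                f"({self.ci_low}, {self.point}, {self.ci_high})"
            )

    def __str__(self) -> str:
        return (
            f"{self.point:.3f} [{self.ci_low:.3f}, {self.ci_high:.3f}] "
            f"(n={self.n_selections})"
        )


@dataclass
class Selection:
    """One 6-stimulus selection group with its decision."""

    block_id: int
    condition: str
    epoch_ids: list[int]
    stimulus_targets: list[int]
    true_target: int
    scores: np.ndarray | None = None
    predicted: int | None = None


def bootstrap_ci(
    flags: Sequence[bool] | np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> AccuracyEstimate:
    """Percentile bootstrap CI for a fraction of correct selections."""
    flags = np.asarray(flags, dtype=float)
    if flags.size == 0:
        raise DomainError("bootstrap_ci requires at least one selection")
    rng = np.random.default_rng(seed)
    point = float(flags.mean())
    idx = rng.integers(0, flags.size, size=(n_boot, flags.size))
    means = flags[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return AccuracyEstimate(
        point=point,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
        n_selections=int(flags.size),
        n_bootstrap=n_boot,
    )


def select_target(scores: Sequence[float], n_targets: int = 6) -> int:
    """Argmax selection rule; ties break to the lowest target index."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (n_targets,) or np.isnan(scores).any():
        raise DomainError(f"expected {n_targets} finite scores, got {scores}")
    return int(np.argmax(scores))


def partition_single_trial_selections(info: pd.DataFrame) -> list[Selection]:
    """Group a block's stimuli into consecutive 6-unique-target selections.

    Round-structured blocks partition exactly into len/6 selections. If a
    consecutive group of six contains a duplicate target (non-round data),
    the function falls back to a greedy scan that collects the next six
    unique targets, logging the event.
    """
    if info["block_id"].nunique() != 1:
        raise DomainError("partition expects epochs of a single block")
    n_targets = 6
    block_id = int(info["block_id"].iloc[0])
    condition = str(info["condition"].iloc[0])
    true_target = int(info["cued_target"].iloc[0])
    stims = info["stimulus_target"].to_numpy(dtype=int)
    ids = info.index.to_numpy()

    selections: list[Selection] = []
    n_full = len(stims) // n_targets
    clean = all(
        len(set(stims[i * n_targets : (i + 1) * n_targets])) == n_targets
        for i in range(n_full)
    )
    if clean:
        groups = [np.arange(i * n_targets, (i + 1) * n_targets) for i in range(n_full)]
    else:
        logger.info(
            "block %d: non-round stimulus order, falling back to greedy grouping",
            block_id,
        )
        groups = []
        current: list[int] = []
        seen: set[int] = set()
        for i, s in enumerate(stims):
            if s in seen:
                continue
            seen.add(int(s))
            current.append(i)
            if len(current) == n_targets:
                groups.append(np.asarray(current))
                current, seen = [], set()
    for g in groups:
        order = g[np.argsort(stims[g])]  # index epochs by target id 0..5
        selections.append(
            Selection(
                block_id=block_id,
                condition=condition,
                epoch_ids=[int(ids[i]) for i in order],
                stimulus_targets=[int(stims[i]) for i in order],
                true_target=true_target,
            )
        )
    return selections


def average_k_repetitions(block_epochs: EpochSet, k: int) -> EpochSet:
    """Average the first ``k`` repetitions of each target into 6 epochs."""
    info = block_epochs.info
    if info["block_id"].nunique() != 1:
        raise DomainError("average_k_repetitions expects a single block")
    counts = info.groupby("stimulus_target")["rep_index"].count()
    if k < 1 or k > int(counts.min()):
        raise DomainError(
            f"k={k} exceeds available repetitions (min {int(counts.min())})"
        )
    rows = []
    data = []
    for tgt in sorted(info["stimulus_target"].unique()):
        mask = (info["stimulus_target"] == tgt) & (info["rep_index"] < k)
        idx = np.flatnonzero(mask.to_numpy())
        data.append(block_epochs.data[idx].mean(axis=0))
        first = info.iloc[idx[0]].copy()
        rows.append(first)
    new_info = pd.DataFrame(rows).reset_index(drop=True)
    new_info["rep_index"] = 0
    return replace(
        block_epochs,
        data=np.stack(data),
        info=new_info,
    )


def _evaluate_block(
    decoder, test_epochs: EpochSet, mode: str, k: int | None
) -> list[Selection]:
    """Score one held-out block and return its decided selections."""
    if mode == "single_trial":
        scores = np.asarray(decoder.score_epochs(test_epochs), dtype=float)
        sels = partition_single_trial_selections(test_epochs.info)
        for sel in sels:
            s = scores[sel.epoch_ids]
            sel.scores = s
            sel.predicted = select_target(s)
        return sels
    if mode == "averaged":
        if k is None:
            raise DomainError("averaged mode requires k")
        avg = average_k_repetitions(test_epochs, k)
        scores = np.asarray(decoder.score_epochs(avg), dtype=float)
        order = np.argsort(avg.info["stimulus_target"].to_numpy())
        s = scores[order]
        sel = Selection(
            block_id=int(avg.info["block_id"].iloc[0]),
            condition=str(avg.info["condition"].iloc[0]),
            epoch_ids=[],
            stimulus_targets=sorted(avg.info["stimulus_target"].astype(int)),
            true_target=int(avg.info["cued_target"].iloc[0]),
            scores=s,
            predicted=select_target(s),
        )
        return [sel]
    raise DomainError(f"unknown evaluation mode {mode!r}")


@dataclass
class CvResult:
    """Pooled block-wise CV outcome with per-fold detail."""

    estimate: AccuracyEstimate
    folds: pd.DataFrame
    selections: list[Selection]
    condition: str | None = None
    decoder: str | None = None

    def summary(self) -> str:
        lines = [
            f"Block-wise CV ({self.condition or 'all'}"
            + (f", {self.decoder}" if self.decoder else "")
            + f"): accuracy {self.estimate}",
            self.folds.to_string(index=False),
        ]
        return "\n".join(lines)


def blockwise_cv(
    epochs: EpochSet,
    decoder_factory: DecoderFactory,
    condition: str | None = None,
    mode: str = "single_trial",
    k: int | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    n_folds_expected: int = 6,
) -> CvResult:
    """Block-wise cross-validation of selection accuracy.

    Folds correspond to stimulation blocks of one condition: train on the
    other 5, test on the held-out block; correctness flags are pooled over
    folds and summarized by a percentile-bootstrap CI.
    """
    if condition is not None:
        epochs = epochs.select((epochs.info["condition"] == condition).to_numpy())
    blocks = sorted(epochs.info["block_id"].unique())
    if len(blocks) != n_folds_expected:
        raise DomainError(
            f"expected {n_folds_expected} blocks, found {len(blocks)}"
        )
    all_sel: list[Selection] = []
    fold_rows = []
    block_ids = epochs.info["block_id"].to_numpy()
    for fold, b in enumerate(blocks):
        train = epochs.select(block_ids != b)
        test = epochs.select(block_ids == b)
        assert not set(train.info["epoch_id"]) & set(test.info["epoch_id"])
        decoder = decoder_factory()
        decoder.fit_epochs(train)
        sels = _evaluate_block(decoder, test, mode, k)
        n_corr = sum(s.predicted == s.true_target for s in sels)
        fold_rows.append(
            dict(fold=fold, block_id=int(b), n_selections=len(sels), n_correct=n_corr)
        )
        all_sel.extend(sels)
    flags = [s.predicted == s.true_target for s in all_sel]
    est = bootstrap_ci(flags, n_boot=n_boot, seed=seed)
    return CvResult(
        estimate=est,
        folds=pd.DataFrame(fold_rows),
        selections=all_sel,
        condition=condition,
    )


def accuracy_by_k(
    epochs: EpochSet,
    decoder_factory: DecoderFactory,
    condition: str | None = None,
    ks: Sequence[int] = tuple(range(1, 11)),
    n_boot: int = 10_000,
    seed: int = 0,
) -> dict[int, AccuracyEstimate]:
    """Accuracy of k-averaged selections for each k, sharing per-fold fits."""
    if condition is not None:
        epochs = epochs.select((epochs.info["condition"] == condition).to_numpy())
    blocks = sorted(epochs.info["block_id"].unique())
    if len(blocks) != 6:
        raise DomainError(f"expected 6 blocks, found {len(blocks)}")
    flags: dict[int, list[bool]] = {k: [] for k in ks}
    block_ids = epochs.info["block_id"].to_numpy()
    for b in blocks:
        decoder = decoder_factory()
        decoder.fit_epochs(epochs.select(block_ids != b))
        test = epochs.select(block_ids == b)
        for k in ks:
            (sel,) = _evaluate_block(decoder, test, "averaged", k)
            flags[k].append(sel.predicted == sel.true_target)
    return {
        k: bootstrap_ci(flags[k], n_boot=n_boot, seed=seed + k) for k in ks
    }


@dataclass
class CrossConditionResult:
    """3x3 (train condition, test condition) accuracy grid."""

    matrix: dict[tuple[str, str], AccuracyEstimate]
    conditions: list[str]
    decoder: str | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for a in self.conditions:
            row = {"train": a}
            for b in self.conditions:
                row[b] = self.matrix[(a, b)].point
            rows.append(row)
        return pd.DataFrame(rows).set_index("train")


def cross_condition_eval(
    epochs: EpochSet,
    decoder_factory: DecoderFactory,
    conditions: Sequence[str] | None = None,
    mode: str = "single_trial",
    k: int | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
) -> CrossConditionResult:
    """Train on 5 blocks of condition A, test on held-out blocks of B.

    Off-diagonal cells rotate the excluded A-fold with the B test-block fold
    index, so the training set always has 5 blocks and all data is used
    symmetrically. Diagonal cells delegate to :func:`blockwise_cv`.
    """
    if conditions is None:
        conditions = sorted(epochs.info["condition"].unique())
    matrix: dict[tuple[str, str], AccuracyEstimate] = {}
    cond_col = epochs.info["condition"].to_numpy()
    block_ids = epochs.info["block_id"].to_numpy()
    blocks_of = {
        c: sorted(epochs.info.loc[cond_col == c, "block_id"].unique())
        for c in conditions
    }
    for c, blist in blocks_of.items():
        if len(blist) != 6:
            raise DomainError(f"condition {c!r} has {len(blist)} blocks, expected 6")
    for a in conditions:
        for b in conditions:
            if a == b:
                matrix[(a, b)] = blockwise_cv(
                    epochs, decoder_factory, condition=a, mode=mode, k=k,
                    n_boot=n_boot, seed=seed,
                ).estimate
                continue
            sels: list[Selection] = []
            for j, test_block in enumerate(blocks_of[b]):
                train_blocks = [blk for i, blk in enumerate(blocks_of[a]) if i != j]
                train = epochs.select(np.isin(block_ids, train_blocks))
                test = epochs.select(block_ids == test_block)
                decoder = decoder_factory()
                decoder.fit_epochs(train)
                sels.extend(_evaluate_block(decoder, test, mode, k))
            flags = [s.predicted == s.true_target for s in sels]
            matrix[(a, b)] = bootstrap_ci(flags, n_boot=n_boot, seed=seed)
    return CrossConditionResult(matrix=matrix, conditions=list(conditions))


def paired_transfer(
    epochs: EpochSet,
    decoder_factory: DecoderFactory,
    train_conditions: Sequence[str] = ("overt", "covert"),
    test_condition: str = "covert",
    mode: str = "single_trial",
    k: int | None = None,
) -> dict[str, float]:
    """Accuracy on one test condition for each calibration condition.

    For every held-out test block (fold j), each training condition
    contributes its 5 blocks with fold index != j, exactly as in
    :func:`cross_condition_eval`; within-condition training excludes the
    test block itself. Returns {train_condition: pooled accuracy} — the
    paired contrast for calibration-transfer experiments, computed without
    the unused cells of the full cross-condition grid.
    """
    cond_col = epochs.info["condition"].to_numpy()
    block_ids = epochs.info["block_id"].to_numpy()
    blocks_of = {
        c: sorted(epochs.info.loc[cond_col == c, "block_id"].unique())
        for c in set(train_conditions) | {test_condition}
    }
    flags: dict[str, list[bool]] = {c: [] for c in train_conditions}
    for j, test_block in enumerate(blocks_of[test_condition]):
        test = epochs.select(block_ids == test_block)
        for cond in train_conditions:
            if cond == test_condition:
                train_blocks = [b for b in blocks_of[cond] if b != test_block]
            else:
                train_blocks = [b for i, b in enumerate(blocks_of[cond]) if i != j]
            train = epochs.select(np.isin(block_ids, train_blocks))
            decoder = decoder_factory()
            decoder.fit_epochs(train)
            sels = _evaluate_block(decoder, test, mode, k)
            flags[cond].extend(s.predicted == s.true_target for s in sels)
    return {c: float(np.mean(v)) for c, v in flags.items()}


def reps_to_threshold(
    curve: Mapping[int, float] | Mapping[int, AccuracyEstimate],
    threshold: float = 0.8,
) -> int | None:
    """Smallest k whose accuracy reaches ``threshold`` (inclusive), else None.

    A None result renders as an en dash in reports, following the convention
    for participants who never reach the 80% effective-operation level.
    """
    best = None
    for k in sorted(curve):
        v = curve[k]
        acc = v.point if isinstance(v, AccuracyEstimate) else float(v)
        if acc >= threshold:
            best = int(k)
            break
    return best


def format_reps(k: int | None) -> str:
    return "–" if k is None else str(k)
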