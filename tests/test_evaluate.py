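"""Selection partitioning, accuracy estimation and cross-validation machinery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from vsabci.decoders import ToeplitzLDA
from vsabci.errors import DomainError
from vsabci.evaluate import (
    AccuracyEstimate,
    accuracy_by_k,
    average_k_repetitions,
    blockwise_cv,
    bootstrap_ci,
    cross_condition_eval,
    format_reps,
    paired_transfer,
    partition_single_trial_selections,
    reps_to_threshold,
    select_target,
)


class TestBootstrap:
    def test_all_correct_gives_degenerate_ci(self):
        est = bootstrap_ci([True] * 30, n_boot=1000)
        assert est.point == 1.0 and est.ci_low == 1.0 and est.ci_high == 1.0

    def test_ci_contains_point(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            flags = rng.random(40) < rng.random()
            if flags.size == 0:
                continue
            est = bootstrap_ci(flags, n_boot=500, seed=1)
            assert est.ci_low <= est.point <= est.ci_high

    def test_coverage_of_known_rate(self):
        """95% percentile CI covers a Bernoulli(0.8) rate in 93-97% of
        1000 replicate experiments (n=200 each)."""
        rng = np.random.default_rng(2024)
        covered = 0
        for i in range(1000):
            flags = rng.random(200) < 0.8
            est = bootstrap_ci(flags, n_boot=2000, seed=i)
            covered += est.ci_low <= 0.8 <= est.ci_high
        assert 930 <= covered <= 970

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            bootstrap_ci([])

    def test_estimate_ordering_enforced(self):
        with pytest.raises(DomainError):
            AccuracyEstimate(point=0.5, ci_low=0.6, ci_high=0.9,
                             n_selections=10, n_bootstrap=100)


class TestSelectTarget:
    def test_argmax(self):
        assert select_target([0.9, 0.1, 0.1, 0.1, 0.1, 0.1]) == 0

    def test_tie_breaks_to_lowest_index(self):
        assert select_target([0.0, 0.1, 0.7, 0.1, 0.7, 0.0]) == 2

    def test_random_scores_hit_chance_level(self):
        """10,000 random-score selections land within 0.02 of 1/6."""
        rng = np.random.default_rng(7)
        scores = rng.standard_normal((10_000, 6))
        truth = rng.integers(0, 6, size=10_000)
        acc = np.mean(scores.argmax(axis=1) == truth)
        assert abs(acc - 1 / 6) < 0.02

    def test_missing_score_rejected(self):
        with pytest.raises(DomainError):
            select_target([0.1, 0.2, np.nan, 0.3, 0.1, 0.0])


class TestPartition:
    def test_default_block_gives_ten_selections(self, covert_epochs):
        block = covert_epochs.select(
            (covert_epochs.info["block_id"] == covert_epochs.info["block_id"].iloc[0]).to_numpy()
        )
        sels = partition_single_trial_selections(block.info)
        assert len(sels) == 10
        for s in sels:
            assert sorted(s.stimulus_targets) == list(range(6))

    def test_six_epoch_block_gives_one_selection(self):
        info = pd.DataFrame(
            dict(block_id=0, condition="overt", cued_target=2,
                 stimulus_target=[3, 1, 0, 5, 2, 4])
        )
        sels = partition_single_trial_selections(info)
        assert len(sels) == 1

    def test_greedy_fallback_on_shuffled_order(self):
        rng = np.random.default_rng(5)
        stims = rng.permutation(np.repeat(np.arange(6), 10))
        info = pd.DataFrame(
            dict(block_id=0, condition="overt", cued_target=0, stimulus_target=stims)
        )
        sels = partition_single_trial_selections(info)
        assert len(sels) >= 1
        for s in sels:
            assert len(set(s.stimulus_targets)) == 6


class TestAverageK:
    def _block(self, epochs):
        b = epochs.info["block_id"].iloc[0]
        return epochs.select((epochs.info["block_id"] == b).to_numpy())

    def test_k1_equals_first_epoch_of_each_target(self, covert_epochs):
        block = self._block(covert_epochs)
        avg = average_k_repetitions(block, 1)
        assert len(avg) == 6
        for i, tgt in enumerate(avg.info["stimulus_target"]):
            first = block.info[
                (block.info["stimulus_target"] == tgt) & (block.info["rep_index"] == 0)
            ].index[0]
            np.testing.assert_array_equal(avg.data[i], block.data[first])

    def test_k_too_large_rejected(self, covert_epochs):
        with pytest.raises(DomainError, match="exceeds"):
            average_k_repetitions(self._block(covert_epochs), 11)

    def test_noise_variance_shrinks_like_one_over_k(self):
        """Averaging k pure-noise epochs reduces variance ~1/k (n=500)."""
        rng = np.random.default_rng(0)
        n_per, k = 500, 5
        data = rng.standard_normal((6 * n_per * k, 2, 10))
        info = pd.DataFrame(
            dict(
                block_id=0, condition="overt", cued_target=0,
                stimulus_target=np.tile(np.repeat(np.arange(6), k), n_per)[: len(data)],
            )
        )
        info["rep_index"] = info.groupby("stimulus_target").cumcount()
        from vsabci.preprocess import EpochSet

        eps = EpochSet(
            data=data, tmin=0.0, tmax=10 / 1000, sfreq=1000.0,
            ch_names=["a", "b"], info=info,
        )
        avg = average_k_repetitions(eps, k)
        ratio = avg.data.var() / data.var()
        assert abs(ratio - 1 / k) < 0.15 / k


class TestBlockwiseCv:
    def test_noise_free_session_perfect(self, separable_session):
        from vsabci.preprocess import standard_chain

        eps = standard_chain(separable_session)
        cv = blockwise_cv(eps, ToeplitzLDA, n_boot=500)
        assert cv.estimate.point == 1.0
        assert (cv.estimate.ci_low, cv.estimate.ci_high) == (1.0, 1.0)

    def test_folds_partition_blocks(self, covert_epochs):
        cv = blockwise_cv(covert_epochs, ToeplitzLDA, n_boot=200)
        assert sorted(cv.folds["block_id"]) == sorted(
            covert_epochs.info["block_id"].unique()
        )
        assert cv.estimate.n_selections == cv.folds["n_selections"].sum()

    def test_label_shuffled_training_is_chance(self, covert_epochs):
        """Destroying the label-feature link drops accuracy to ~1/6."""

        class ShuffledFit:
            def __init__(self):
                self.inner = ToeplitzLDA()
                self.rng = np.random.default_rng(11)

            def fit_epochs(self, eps):
                info = eps.info.copy()
                info["is_target"] = self.rng.permutation(
                    info["is_target"].to_numpy()
                )
                self.inner.fit_epochs(dataclasses.replace(eps, info=info))
                return self

            def score_epochs(self, eps):
                return self.inner.score_epochs(eps)

        cv = blockwise_cv(covert_epochs, ShuffledFit, n_boot=2000, seed=3)
        assert cv.estimate.ci_low - 0.02 <= 1 / 6 <= cv.estimate.ci_high + 0.02

    def test_missing_blocks_rejected(self, covert_epochs):
        half = covert_epochs.select(
            covert_epochs.info["block_id"].isin(
                sorted(covert_epochs.info["block_id"].unique())[:3]
            ).to_numpy()
        )
        with pytest.raises(DomainError, match="blocks"):
            blockwise_cv(half, ToeplitzLDA)


class TestCrossCondition:
    def test_diagonal_matches_blockwise_cv(self, default_epochs):
        res = cross_condition_eval(default_epochs, ToeplitzLDA, n_boot=300, seed=4)
        for cond in res.conditions:
            cv = blockwise_cv(
                default_epochs, ToeplitzLDA, condition=cond, n_boot=300, seed=4
            )
            assert res.matrix[(cond, cond)].point == cv.estimate.point

    def test_identical_profiles_make_offdiagonal_match_diagonal(self):
        """With exchangeable conditions, transfer equals within-condition CV."""
        from vsabci.paradigm import default_condition_profiles, simulate_session
        from vsabci.preprocess import standard_chain

        overt = default_condition_profiles()["overt"]
        profiles = {
            "overt": overt,
            "covert": dataclasses.replace(overt, condition="covert"),
        }
        s = simulate_session(profiles=profiles, seed=31, conditions=("overt", "covert"))
        eps = standard_chain(s)
        res = cross_condition_eval(
            eps, ToeplitzLDA, conditions=["overt", "covert"], n_boot=1000, seed=0
        )
        off = res.matrix[("overt", "covert")]
        diag = res.matrix[("covert", "covert")]
        assert off.ci_low <= diag.ci_high and diag.ci_low <= off.ci_high

    def test_summary_grid_shape(self, default_epochs):
        res = cross_condition_eval(default_epochs, ToeplitzLDA, n_boot=200)
        grid = res.summary()
        assert grid.shape == (3, 3)


class TestAccuracyByK:
    def test_monotone_trend_in_k(self):
        """Mean accuracy rises with the number of averaged repetitions."""
        from vsabci.paradigm import simulate_session
        from vsabci.preprocess import standard_chain

        curves = []
        for seed in range(20):
            s = simulate_session(seed=4000 + seed, conditions=("overt",))
            eps = standard_chain(s)
            curve = accuracy_by_k(eps, ToeplitzLDA, ks=(1, 2, 4, 6, 8, 10), n_boot=50)
            curves.append([curve[k].point for k in (1, 2, 4, 6, 8, 10)])
        mean_curve = np.mean(curves, axis=0)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(np.arange(len(mean_curve)), mean_curve)
        assert rho > 0.6
        assert mean_curve[-1] >= mean_curve[0]


class TestRepsToThreshold:
    def test_first_crossing(self):
        assert reps_to_threshold({1: 0.5, 2: 0.7, 3: 0.85, 4: 0.9}) == 3

    def test_never_reached_is_none_rendered_dash(self):
        curve = {k: 0.5 for k in range(1, 11)}
        assert reps_to_threshold(curve) is None
        assert format_reps(None) == "–"

    def test_boundary_inclusive(self):
        assert reps_to_threshold({1: 0.8, 2: 0.9}) == 1

    def test_accepts_estimates(self):
        est = AccuracyEstimate(0.9, 0.8, 1.0, 6, 100)
        assert reps_to_threshold({1: est}) == 1


def test_paired_transfer_matches_cross_condition(default_epochs):
    """The two-cell fast path agrees with the full grid point estimates."""
    res = cross_condition_eval(
        default_epochs, ToeplitzLDA, conditions=["overt", "covert"], n_boot=200
    )
    acc = paired_transfer(
        default_epochs, ToeplitzLDA, train_conditions=("overt", "covert"),
        test_condition="covert",
    )
    assert acc["overt"] == pytest.approx(res.matrix[("overt", "covert")].point)
    assert acc["covert"] == pytest.approx(res.matrix[("covert", "covert")].point)
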