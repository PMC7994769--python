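import numpy as np
import pandas as pd
import pytest

import breathloop as bl
from breathloop.errors import DesignError, SummaryError

from conftest import synthetic_summaries


def make_record(rates, scores, stales=None, condition=bl.WITH_FEEDBACK,
                participant="P01", session=0):
    """Hand-built session record for summary tests."""
    n = len(rates)
    config = bl.SessionConfig(condition=condition, participant_id=participant,
                              session_index=session)
    frame = pd.DataFrame({
        "time": np.arange(n) / config.tick_rate,
        "raw": np.zeros(n),
        "rate": rates,
        "score": scores,
        "aperture": np.ones(n),
        "light": np.ones(n),
        "stale": stales if stales is not None else np.zeros(n, dtype=int),
    })
    return bl.SessionRecord(config=config, frame=frame)


class TestSummaries:
    def test_constant_record_summary(self):
        rec = make_record([6.0] * 10, [1.0] * 10)
        s = bl.summarize_session(rec)
        assert (s.mean_rate, s.mean_score) == (6.0, 1.0)
        assert s.time_in_band == 1.0

    def test_half_and_half_scores_average(self):
        rec = make_record([6.0] * 10, [1.0] * 5 + [0.0] * 5)
        assert bl.summarize_session(rec).mean_score == 0.5

    def test_warm_up_and_stale_ticks_excluded(self):
        rates = [np.nan] * 4 + [6.0] * 4 + [20.0] * 2
        scores = [0.5] * 4 + [1.0] * 4 + [0.2] * 2
        stales = [0] * 8 + [1] * 2  # the 20-rate ticks are stale
        s = bl.summarize_session(make_record(rates, scores, stales))
        assert s.mean_rate == 6.0
        assert s.mean_score == 1.0
        assert s.n_ticks_used == 4

    def test_no_defined_estimates_is_an_error(self):
        with pytest.raises(SummaryError):
            bl.summarize_session(make_record([np.nan] * 5, [0.5] * 5))


class TestQuadFit:
    X = np.linspace(5.0, 20.0, 10)
    TRUE = (0.004, -0.12, 1.3)

    def _summaries(self, y):
        return pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(len(self.X))],
            "session_index": range(len(self.X)),
            "condition": bl.WITH_FEEDBACK,
            "mean_rate": self.X,
            "mean_score": y,
        })

    def test_exact_recovery_on_noise_free_points(self):
        a2, a1, a0 = self.TRUE
        y = a2 * self.X**2 + a1 * self.X + a0
        fit = bl.fit_quadratic(self._summaries(y), n_boot=200, seed=0)
        assert np.allclose(fit.coefficients, self.TRUE, atol=1e-9)

    def test_noise_free_band_has_zero_width(self):
        a2, a1, a0 = self.TRUE
        y = a2 * self.X**2 + a1 * self.X + a0
        fit = bl.fit_quadratic(self._summaries(y), n_boot=500, seed=1)
        assert float(np.max(fit.upper - fit.lower)) < 1e-8

    def test_matches_brute_force_normal_equations(self):
        rng = np.random.default_rng(3)
        y = 0.9 - 0.002 * (self.X - 10) ** 2 + rng.normal(0, 0.05, self.X.size)
        fit = bl.fit_quadratic(self._summaries(y), n_boot=100, seed=2)
        V = np.vander(self.X, 3)
        brute = np.linalg.solve(V.T @ V, V.T @ y)
        assert np.allclose(fit.coefficients, brute, atol=1e-8)

    def test_band_brackets_point_prediction(self):
        rng = np.random.default_rng(4)
        y = 0.9 - 0.002 * (self.X - 10) ** 2 + rng.normal(0, 0.05, self.X.size)
        fit = bl.fit_quadratic(self._summaries(y), n_boot=500, seed=5)
        point = fit.predict(fit.grid)
        assert np.all(fit.lower <= point) and np.all(point <= fit.upper)

    def test_band_covers_true_curve_at_most_grid_points(self):
        """Pointwise 95% bootstrap band should capture the generating curve
        at >= 90% of (replication, grid point) pairs."""
        a2, a1, a0 = self.TRUE
        hits = total = 0
        for rep in range(60):
            rng = np.random.default_rng(100 + rep)
            y = a2 * self.X**2 + a1 * self.X + a0 + rng.normal(0, 0.04, self.X.size)
            fit = bl.fit_quadratic(self._summaries(y), n_boot=400, seed=rep)
            truth = a2 * fit.grid**2 + a1 * fit.grid + a0
            hits += int(np.sum((fit.lower <= truth) & (truth <= fit.upper)))
            total += fit.grid.size
        assert hits / total >= 0.90

    def test_fewer_than_three_distinct_rates_rejected(self):
        frame = self._summaries(np.ones(self.X.size))
        frame["mean_rate"] = [5.0, 5.0, 8.0, 8.0, 5.0, 8.0, 5.0, 8.0, 5.0, 8.0]
        with pytest.raises(DesignError, match="distinct"):
            bl.fit_quadratic(frame, n_boot=10, seed=0)

    def test_seed_required(self):
        y = np.ones(self.X.size)
        with pytest.raises(DesignError):
            bl.fit_quadratic(self._summaries(y), n_boot=10)


class TestMeanDifference:
    def test_identical_conditions_give_zero_effect(self):
        rng = np.random.default_rng(0)
        frame = synthetic_summaries(8, rng, score_offset=0.0, rate_sd=0.0, score_sd=0.0)
        md = bl.mean_difference(frame, "mean_rate", n_boot=200, seed=0)
        assert md.effect == 0.0
        assert md.ci_low <= 0.0 <= md.ci_high

    def test_fixed_seed_is_bitwise_reproducible(self):
        rng = np.random.default_rng(1)
        frame = synthetic_summaries(9, rng, score_offset=0.2)
        a = bl.mean_difference(frame, "mean_score", n_boot=500, seed=7)
        b = bl.mean_difference(frame, "mean_score", n_boot=500, seed=7)
        assert (a.effect, a.ci_low, a.ci_high) == (b.effect, b.ci_low, b.ci_high)

    def test_missing_condition_rejected(self):
        rng = np.random.default_rng(2)
        frame = synthetic_summaries(4, rng)
        only_with = frame[frame["condition"] == bl.WITH_FEEDBACK]
        with pytest.raises(DesignError, match="missing"):
            bl.mean_difference(only_with, "mean_rate", n_boot=10, seed=0)

    def test_unpaired_variant_runs_and_brackets_effect(self):
        rng = np.random.default_rng(3)
        frame = synthetic_summaries(12, rng, rate_offset=-2.0)
        md = bl.mean_difference(frame, "mean_rate", pairing="unpaired",
                                n_boot=500, seed=0)
        assert md.ci_low <= md.effect <= md.ci_high
        assert md.effect < 0

    def test_injected_score_effect_is_covered_95_percent(self):
        """Known +0.2 score effect: the paired 95% CI should cover it in
        roughly 95% of replications (tolerance 4 percentage points).

        Run with enough participants that the percentile interval's nominal
        level is attainable; at very small n it is known to undercover."""
        hits = 0
        reps = 200
        for rep in range(reps):
            rng = np.random.default_rng(10_000 + rep)
            frame = synthetic_summaries(50, rng, score_offset=0.2, n_sessions=8)
            md = bl.mean_difference(frame, "mean_score", n_boot=1000, seed=rep)
            hits += md.ci_low <= 0.2 <= md.ci_high
        assert abs(hits / reps - 0.95) <= 0.04

    def test_ci_width_shrinks_with_more_participants(self):
        def width(n, seed):
            rng = np.random.default_rng(seed)
            frame = synthetic_summaries(n, rng, score_offset=0.2)
            md = bl.mean_difference(frame, "mean_score", n_boot=500, seed=seed)
            return md.ci_high - md.ci_low

        small = np.median([width(10, s) for s in range(10)])
        large = np.median([width(40, s) for s in range(10)])
        assert large < small

    def test_label_permutation_null_is_covered_95_percent(self):
        """Swapping condition labels within participants kills the effect;
        the CI should then cover zero at roughly the nominal rate."""
        rng = np.random.default_rng(5)
        base = synthetic_summaries(20, rng, score_offset=0.0)
        hits = 0
        reps = 200
        for rep in range(reps):
            perm_rng = np.random.default_rng(20_000 + rep)
            frame = base.copy()
            for pid in frame["participant_id"].unique():
                if perm_rng.random() < 0.5:
                    sel = frame["participant_id"] == pid
                    frame.loc[sel, "condition"] = frame.loc[sel, "condition"].map(
                        {bl.WITH_FEEDBACK: bl.WITHOUT_FEEDBACK,
                         bl.WITHOUT_FEEDBACK: bl.WITH_FEEDBACK})
            md = bl.mean_difference(frame, "mean_score", n_boot=500, seed=rep)
            hits += md.ci_low <= 0.0 <= md.ci_high
        assert 0.90 <= hits / reps <= 0.995


class TestTrends:
    def test_group_rates_decrease_with_decreasing_generator(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(6):
            for j in range(8):
                cond = bl.WITH_FEEDBACK if j % 2 == 0 else bl.WITHOUT_FEEDBACK
                rows.append(dict(participant_id=f"P{i}", session_index=j, condition=cond,
                                 mean_rate=16.0 - 1.0 * j + rng.normal(0, 0.05),
                                 mean_score=0.5 + 0.05 * j))
        trends = bl.session_trends(pd.DataFrame(rows))
        group = (trends[trends["level"] == "group"]
                 .groupby("session_index")["mean_rate"].mean())
        assert (np.diff(group.to_numpy()) < 0).all()

    def test_single_session_gives_one_group_row(self):
        frame = pd.DataFrame([dict(participant_id="P1", session_index=0,
                                   condition=bl.WITH_FEEDBACK,
                                   mean_rate=8.0, mean_score=0.9)])
        trends = bl.session_trends(frame)
        assert len(trends[trends["level"] == "group"]) == 1

    def test_condition_offset_produces_within_participant_zigzag(self):
        """With alternating conditions and a negative feedback offset, each
        participant's rate is lower on with-feedback sessions than the mean
        of their neighboring without-feedback sessions."""
        design = bl.PilotDesign(n_participants=3, n_sessions=6, session_duration=30.0,
                                learning=bl.LearningModel(per_session_drop=0.0,
                                                          feedback_offset=2.0),
                                seed=2)
        sessions = bl.simulate_pilot(design)
        for pid in {s.participant_id for s in sessions}:
            own = sorted((s.session_index, s.model_rate, s.condition)
                         for s in sessions if s.participant_id == pid)
            for j in range(1, len(own) - 1):
                idx, rate, cond = own[j]
                neighbors = (own[j - 1][1] + own[j + 1][1]) / 2
                if cond == bl.WITH_FEEDBACK:
                    assert rate < neighbors
                else:
                    assert rate > neighbors
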