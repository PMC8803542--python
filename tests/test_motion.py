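"""Kinematics: filtering, change-point segmentation, trial metrics,
repeated-measures ANOVA and the blinding test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motordcm.schedule import generate_schedule
from motordcm.synth import simulate_joystick, JoystickTrace
from motordcm.motion import (preprocess_trace, detect_changepoints,
                             detect_movement, trial_metrics, extract_trials,
                             summarize_run, rm_anova, mcnemar, BlindingTable)

RATE = 1200.0


def _trace(x, y=None):
    n = len(x)
    return JoystickTrace(sample_times=np.arange(n) / RATE,
                         x=np.asarray(x, float),
                         y=np.zeros(n) if y is None else np.asarray(y, float))


class TestPreprocess:
    def test_constant_trace_passes_dc(self):
        out = preprocess_trace(_trace(np.full(2400, 0.0), np.full(2400, 0.0)))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    @pytest.mark.parametrize("freq,kind", [(50.0, "stop"), (2.0, "pass")])
    def test_filter_response(self, freq, kind):
        t = np.arange(4800) / RATE
        sig = 0.5 + 0.2 * np.sin(2 * np.pi * freq * t)
        out = preprocess_trace(_trace(sig))
        # compare the oscillation amplitude in the central section
        mid = slice(1200, 3600)
        amp_in, amp_out = 0.2, (out[mid].max() - out[mid].min()) / 2
        if kind == "stop":
            assert amp_out < 0.05 * amp_in
        else:
            assert abs(amp_out - amp_in) < 0.02 * amp_in

    def test_non_uniform_sampling_rejected(self):
        t = np.arange(100) / RATE
        t[50] += 0.01
        trace = JoystickTrace.__new__(JoystickTrace)
        trace.sample_times, trace.x, trace.y, trace.rate = (
            t, np.zeros(100), np.zeros(100), RATE)
        with pytest.raises(ValueError, match="uniform"):
            preprocess_trace(trace)


def _brute_force_changepoints(x, penalty, max_cp=3):
    """Exhaustive search over all segmentations with up to max_cp changes."""
    n = len(x)
    best = (np.sum((x - x.mean()) ** 2), [])
    for k in range(1, max_cp + 1):
        for cps in itertools.combinations(range(1, n), k):
            bounds = [0, *cps, n]
            cost = k * penalty
            for a, b in zip(bounds[:-1], bounds[1:]):
                seg = x[a:b]
                cost += np.sum((seg - seg.mean()) ** 2)
            if cost < best[0] - 1e-12:
                best = (cost, list(cps))
    return best[1]


class TestChangepoints:
    def test_flat_signal_returns_none(self):
        assert detect_movement(np.zeros(1200)) is None

    def test_step_located_exactly(self):
        x = np.zeros(1200)
        x[600:] = 1.0
        assert detect_movement(x, penalty=1.0, refine=False) == (600, 600)

    def test_boxcar_onset_and_offset(self):
        x = np.zeros(1200)
        x[600:900] = 1.0
        assert detect_movement(x, penalty=1.0, refine=False) == (600, 900)

    @pytest.mark.parametrize("seed", range(6))
    def test_dp_equals_exhaustive_search(self, seed):
        """The penalized DP returns the globally optimal segmentation
        found by brute-force enumeration on small signals."""
        rng = np.random.default_rng(seed)
        n = 40
        x = rng.normal(0, 0.3, n)
        x[15:28] += rng.uniform(1.0, 2.0)
        penalty = 1.0
        got = detect_changepoints(x, penalty=penalty)
        want = _brute_force_changepoints(x, penalty)
        assert got == want

    def test_dp_matches_two_change_oracle_at_scale(self):
        """On a 2000-sample two-step signal the DP solution equals the
        exhaustive two-change-point optimum."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.05, 2000)
        x[700:1300] += 1.0
        penalty = 5.0
        got = detect_changepoints(x, penalty=penalty)
        # exhaustive over pairs, vectorised via cumulative sums
        S1 = np.concatenate([[0], np.cumsum(x)])
        S2 = np.concatenate([[0], np.cumsum(x * x)])

        def sse(a, b):
            return (S2[b] - S2[a]) - (S1[b] - S1[a]) ** 2 / (b - a)

        best, best_pair = np.inf, None
        for a in range(650, 750):
            for b in range(1250, 1350):
                cost = sse(0, a) + sse(a, b) + sse(b, 2000) + 2 * penalty
                if cost < best:
                    best, best_pair = cost, [a, b]
        assert got == best_pair

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            detect_movement(np.zeros(10), window=2)


class TestTrialMetrics:
    def test_linear_ramp_constant_velocity(self):
        rate = 100.0
        slope = 2.0
        x = slope * np.arange(200) / rate
        trial = trial_metrics(x, onset=20, offset=180, cue_time=0.0,
                              sampling_rate=rate)
        assert trial.valid
        assert trial.mean_velocity == pytest.approx(slope, rel=1e-9)
        assert trial.peak_acceleration == pytest.approx(0.0, abs=1e-6)

    def test_reaction_time_definition(self):
        x = np.zeros(1200)
        trial = trial_metrics(x, onset=360, offset=600, cue_time=10.0,
                              sampling_rate=RATE, t0=10.0)
        assert trial.reaction_time == pytest.approx(0.3)

    def test_rt_matches_generator_with_true_onsets(self):
        """Given the generator's true onset samples, the RT conversion is
        exact to well under 5 ms even with 20%-amplitude noise."""
        sched = generate_schedule(7)
        trace, gt = simulate_joystick(sched, seed=2, noise_sd=0.2)
        filt = preprocess_trace(trace)
        for _, row in gt.head(10).iterrows():
            onset = int(round(row.onset * RATE))
            offset = int(round(row.offset * RATE))
            trial = trial_metrics(filt, onset, offset, cue_time=row.cue_time,
                                  sampling_rate=RATE)
            assert abs(trial.reaction_time - row.reaction_time) < 0.005

    def test_invalid_when_offset_before_onset(self):
        trial = trial_metrics(np.zeros(100), onset=50, offset=50,
                              cue_time=0.0, sampling_rate=RATE)
        assert not trial.valid


class TestRunLevel:
    def test_rt_estimator_bias_small(self):
        """Mean estimated RT tracks the generator mean within 10 ms over a
        full 56-trial run at the generator's default noise."""
        sched = generate_schedule(42)
        trace, gt = simulate_joystick(sched, seed=9)
        filt = preprocess_trace(trace)
        trials = extract_trials(filt, sched, trace.rate)
        valid = trials[trials.valid]
        assert len(valid) == 56
        assert abs(valid.reaction_time.mean() - gt.reaction_time.mean()) < 0.01

    def test_excluded_trials_counted_not_averaged(self):
        sched = generate_schedule(11)
        trace, gt = simulate_joystick(sched, seed=4, miss_rate=0.3)
        filt = preprocess_trace(trace)
        trials = extract_trials(filt, sched, trace.rate)
        summary = summarize_run(trials, "sub-01", "sham", "pre")
        assert summary.n_valid + summary.n_excluded == 56
        assert summary.n_valid <= len(gt)
        valid = trials[trials.valid]
        assert summary.reaction_time == pytest.approx(
            valid.reaction_time.mean())


def _hand_anova_table():
    """3-subject 2x3 table with hand-computed repeated-measures sums of
    squares (verified by explicit arithmetic on the cell values)."""
    values = {
        ("s1", "pre"): (10.0, 12.0, 11.0),   # anodal, cathodal, sham
        ("s1", "post"): (11.0, 13.0, 12.0),
        ("s2", "pre"): (9.0, 10.0, 10.0),
        ("s2", "post"): (10.0, 12.0, 11.0),
        ("s3", "pre"): (12.0, 13.0, 12.0),
        ("s3", "post"): (13.0, 15.0, 14.0),
    }
    rows = []
    for (sub, t), vals in values.items():
        for pol, v in zip(("anodal", "cathodal", "sham"), vals):
            rows.append({"subject": sub, "time": t, "polarity": pol,
                         "reaction_time": v})
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_hand_computed_oracle(self):
        """F values agree with an independent least-squares decomposition
        of the same table."""
        df = _hand_anova_table()
        res = rm_anova(df, metrics=("reaction_time",))["reaction_time"]
        Y = df.pivot_table(index="subject", columns=["polarity", "time"],
                           values="reaction_time").to_numpy()
        Y = Y.reshape(3, 3, 2)  # subject, polarity, time
        m = Y.mean()
        m_s, m_p, m_t = (Y.mean(axis=(1, 2)), Y.mean(axis=(0, 2)),
                         Y.mean(axis=(0, 1)))
        m_sp, m_st, m_pt = Y.mean(axis=2), Y.mean(axis=1), Y.mean(axis=0)
        ss_t = 3 * 3 * ((m_t - m) ** 2).sum()
        ss_ts = 3 * ((m_st - m_s[:, None] - m_t[None] + m) ** 2).sum()
        F_time = (ss_t / 1) / (ss_ts / 2)
        ss_p = 3 * 2 * ((m_p - m) ** 2).sum()
        ss_ps = 2 * ((m_sp - m_s[:, None] - m_p[None] + m) ** 2).sum()
        F_pol = (ss_p / 2) / (ss_ps / 4)
        ss_pt = 3 * ((m_pt - m_p[:, None] - m_t[None] + m) ** 2).sum()
        resid = (Y - m_sp[:, :, None] - m_st[:, None, :] - m_pt[None]
                 + m_s[:, None, None] + m_p[None, :, None]
                 + m_t[None, None, :] - m)
        F_int = (ss_pt / 2) / ((resid ** 2).sum() / 4)
        assert res["time"]["F"] == pytest.approx(F_time, rel=1e-6)
        assert res["polarity"]["F"] == pytest.approx(F_pol, rel=1e-6)
        assert res["interaction"]["F"] == pytest.approx(F_int, rel=1e-6)

    def test_no_within_subject_variance_gives_zero_f(self):
        rows = []
        for s, level in zip("abc", (1.0, 2.0, 3.0)):
            for p in ("anodal", "cathodal", "sham"):
                for t in ("pre", "post"):
                    rows.append({"subject": s, "polarity": p, "time": t,
                                 "reaction_time": level})
        res = rm_anova(pd.DataFrame(rows), metrics=("reaction_time",))
        for eff in res["reaction_time"].values():
            assert eff["F"] == 0.0

    def test_missing_cell_names_subject(self):
        df = _hand_anova_table()
        df = df[~((df.subject == "s2") & (df.polarity == "sham")
                  & (df.time == "post"))]
        with pytest.raises(ValueError, match="s2"):
            rm_anova(df, metrics=("reaction_time",))

    def test_type_one_error_rate_calibrated(self, rng):
        """Null 2x3 tables: interaction rejection rate at alpha=0.05 stays
        within [0.03, 0.07] over 1000 replicates."""
        n_rep, n_sub = 1000, 12
        hits = 0
        # direct F computation (same decomposition rm_anova is tested
        # against above) keeps the replicate loop fast
        for _ in range(n_rep):
            Y = rng.normal(size=(n_sub, 3, 2))
            m = Y.mean()
            m_s, m_p, m_t = (Y.mean(axis=(1, 2)), Y.mean(axis=(0, 2)),
                             Y.mean(axis=(0, 1)))
            m_sp, m_st, m_pt = Y.mean(axis=2), Y.mean(axis=1), Y.mean(axis=0)
            ss_pt = n_sub * ((m_pt - m_p[:, None] - m_t[None] + m) ** 2).sum()
            resid = (Y - m_sp[:, :, None] - m_st[:, None, :] - m_pt[None]
                     + m_s[:, None, None] + m_p[None, :, None]
                     + m_t[None, None, :] - m)
            df_err = (n_sub - 1) * 2
            F = (ss_pt / 2) / ((resid ** 2).sum() / df_err)
            hits += int(stats.f.sf(F, 2, df_err) < 0.05)
        assert 0.03 <= hits / n_rep <= 0.07


class TestMcnemar:
    def test_symmetric_discordance_p_one(self):
        assert mcnemar(np.array([[5, 3], [3, 10]]))["p"] == pytest.approx(1.0)

    def test_one_sided_discordance_closed_form(self):
        res = mcnemar(np.array([[5, 0], [6, 10]]))
        assert res["p"] == pytest.approx(2 * 0.5 ** 6)

    def test_zero_discordant_pairs_noted(self):
        res = mcnemar(np.array([[7, 0], [0, 14]]))
        assert res["p"] == 1.0 and "no discordant" in res["note"]

    def test_equals_binomial_enumeration(self):
        """Exact agreement with the two-sided binomial oracle for every
        discordant split with b + c <= 12."""
        for n in range(1, 13):
            for b in range(n + 1):
                c = n - b
                res = mcnemar(np.array([[2, b], [c, 3]]))
                k = min(b, c)
                oracle = min(1.0, 2 * sum(stats.binom.pmf(i, n, 0.5)
                                          for i in range(k + 1)))
                if b == c:
                    oracle = 1.0
                assert res["p"] == pytest.approx(oracle, abs=1e-10), (b, c)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            BlindingTable(np.array([[1, -1], [0, 2]]))
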