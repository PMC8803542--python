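"""Synthetic-data generators: cohorts, BOLD runs, volumes, joystick,
blinding."""

import numpy as np
import pytest

from motordcm.dcm.model import ConnectivityModel
from motordcm.schedule import generate_schedule
from motordcm import synth
from motordcm.synth import (CohortSpec, GroundTruthEffects, generate_cohort,
                            session_model, simulate_session_bold,
                            embed_volumes, simulate_joystick,
                            simulate_blinding, volumes_for)


class TestCohort:
    def test_session_count_conserved(self):
        man = generate_cohort(CohortSpec(n_subjects=21, seed=0),
                              GroundTruthEffects())
        assert man["n_sessions"] == 126
        assert len(man["subjects"]) == 21
        assert all(len(s["sessions"]) == 6 for s in man["subjects"])

    def test_null_effects_make_pre_equal_post(self):
        man = generate_cohort(CohortSpec(n_subjects=3, seed=5),
                              GroundTruthEffects())
        for s in range(3):
            for pol in ("anodal", "cathodal", "sham"):
                pre = session_model(man, s, pol, "pre")
                post = session_model(man, s, pol, "post")
                np.testing.assert_array_equal(pre.a_off, post.a_off)
                np.testing.assert_array_equal(pre.a_self, post.a_self)

    def test_shift_applied_to_named_connection_only(self):
        effects = GroundTruthEffects(
            shifts={"cathodal": {"A:THA->M1": 0.2}})
        man = generate_cohort(CohortSpec(n_subjects=2, seed=1), effects)
        pre = session_model(man, 0, "cathodal", "pre")
        post = session_model(man, 0, "cathodal", "post")
        diff = post.a_off - pre.a_off
        assert diff[0, 2] == pytest.approx(0.2)   # to-M1 from-THA
        diff[0, 2] = 0.0
        np.testing.assert_allclose(diff, 0.0)
        for pol in ("anodal", "sham"):
            np.testing.assert_array_equal(
                session_model(man, 0, pol, "pre").a_off,
                session_model(man, 0, pol, "post").a_off)

    def test_unknown_connection_rejected(self):
        with pytest.raises(KeyError, match="unknown connection"):
            GroundTruthEffects(shifts={"anodal": {"A:THA->BOGUS": 0.1}})

    def test_sham_shift_rejected(self):
        with pytest.raises(ValueError, match="sham"):
            GroundTruthEffects(shifts={"sham": {"A:THA->M1": 0.1}})

    def test_determinism(self):
        a = generate_cohort(CohortSpec(n_subjects=2, seed=9),
                            GroundTruthEffects.default("exp2"))
        b = generate_cohort(CohortSpec(n_subjects=2, seed=9),
                            GroundTruthEffects.default("exp2"))
        assert a == b

    def test_null_fidelity_post_minus_pre_centred(self):
        """With zero shifts the post-pre parameter differences are exactly
        zero by construction across many seeds (the baseline is drawn
        once per subject)."""
        max_abs = []
        for seed in range(50):
            man = generate_cohort(CohortSpec(n_subjects=1, seed=seed),
                                  GroundTruthEffects())
            pre = session_model(man, 0, "anodal", "pre")
            post = session_model(man, 0, "anodal", "post")
            max_abs.append(np.abs(post.a_off - pre.a_off).max())
        assert np.mean(max_abs) < 1e-12


class TestBold:
    def test_volume_counts_match_acquisition_models(self, schedule):
        assert volumes_for(schedule, 2.0) == 160
        assert volumes_for(schedule, 2.7) == 119

    def test_no_input_coupling_gives_flat_run(self, schedule):
        m = ConnectivityModel(np.zeros((4, 4)), np.zeros(4), np.zeros(4),
                              np.zeros(4))
        run = simulate_session_bold(m, schedule, TR=2.0, noise_sd=0.0)
        np.testing.assert_allclose(run.node_timeseries, 0.0, atol=1e-10)

    def test_noise_and_truth_recorded(self, schedule, stable_model):
        run = simulate_session_bold(stable_model, schedule, TR=2.0,
                                    noise_sd=0.1, relative_noise=True,
                                    seed=3)
        assert run.node_timeseries.shape == (160, 4)
        resid = run.node_timeseries - run.ground_truth
        np.testing.assert_allclose(resid.std(axis=0),
                                   0.1 * run.ground_truth.std(axis=0),
                                   rtol=0.35)

    def test_run_must_cover_schedule(self, schedule, stable_model):
        with pytest.raises(ValueError, match="cover"):
            simulate_session_bold(stable_model, schedule, TR=2.0,
                                  n_volumes=100)

    def test_unstable_model_rejected(self, schedule):
        m = ConnectivityModel(np.full((4, 4), 0.8), np.zeros(4),
                              np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError, match="unstable"):
            simulate_session_bold(m, schedule, TR=2.0)


class TestEmbedVolumes:
    def test_centre_voxel_tracks_node_series(self, schedule, stable_model):
        run = simulate_session_bold(stable_model, schedule, TR=2.0,
                                    noise_sd=0.0)
        coords = synth.GROUP_COORDINATES["exp1"]
        img = embed_volumes(run, coords, smooth_noise_sd=0.0)
        inv = np.linalg.inv(img.affine)
        data = np.asarray(img.dataobj)
        for r, (region, coord) in enumerate(coords.items()):
            ijk = np.round(inv @ np.append(coord, 1.0))[:3].astype(int)
            series = data[tuple(ijk)]
            node = run.node_timeseries[:, r]
            assert np.corrcoef(series, node)[0, 1] > 0.999999

    def test_coordinate_outside_grid_names_region(self, schedule,
                                                  stable_model):
        run = simulate_session_bold(stable_model, schedule, TR=2.0,
                                    noise_sd=0.0)
        with pytest.raises(ValueError, match="M1"):
            embed_volumes(run, {"M1": (500.0, 0.0, 0.0)})

    def test_empty_region_list_gives_pure_noise(self, schedule,
                                                stable_model):
        run = simulate_session_bold(stable_model, schedule, TR=2.0,
                                    noise_sd=0.0)
        img = embed_volumes(run, {}, smooth_noise_sd=0.5, seed=1)
        data = np.asarray(img.dataobj)
        assert data.std() == pytest.approx(0.5, rel=0.05)


class TestJoystick:
    def test_all_missed_gives_flat_noise(self, schedule):
        trace, gt = simulate_joystick(schedule, miss_rate=1.0 - 1e-12,
                                      noise_sd=0.01, seed=0)
        assert len(gt) == 0
        assert np.abs(trace.x).max() < 0.1

    def test_noiseless_fixed_latency_onset_exact(self, schedule):
        trace, gt = simulate_joystick(schedule, latency_mean=0.3,
                                      latency_sd=0.0, noise_sd=0.0, seed=0)
        cue = np.sort(schedule.cue_onsets)[0]
        above = np.flatnonzero(trace.x > 0)
        first = trace.sample_times[above[0]]
        assert first == pytest.approx(cue + 0.3, abs=1.5 / trace.rate)

    def test_full_run_yields_56_movements(self, schedule):
        _, gt = simulate_joystick(schedule, miss_rate=0.0, seed=1)
        assert len(gt) == 56

    def test_overlapping_movements_rejected(self, schedule):
        with pytest.raises(ValueError, match="overlap"):
            simulate_joystick(schedule, movement_duration=2.5)


class TestBlinding:
    def test_perfect_judgement_all_concordant(self):
        _, table = simulate_blinding(21, 1.0, 1.0, seed=0)
        assert table[0, 0] == 21
        assert table[0, 1] == table[1, 0] == table[1, 1] == 0

    def test_one_record_per_subject(self):
        df, table = simulate_blinding(21, 0.5, 0.5, seed=2)
        assert len(df) == 21
        assert table.sum() == 21

    def test_discordant_counts_near_binomial_expectation(self):
        """p_active=0.8, p_sham=0.2: E[b]/n = 0.8*0.8 = 0.64 and
        E[c]/n = 0.2*0.2 = 0.04 (independent judgements)."""
        n = 4000
        _, table = simulate_blinding(n, 0.8, 0.2, seed=7)
        b, c = table[0, 1], table[1, 0]
        assert abs(b / n - 0.64) < 3 * np.sqrt(0.64 * 0.36 / n)
        assert abs(c / n - 0.04) < 3 * np.sqrt(0.04 * 0.96 / n)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            simulate_blinding(5, 1.2, 0.5)
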