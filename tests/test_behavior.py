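import dataclasses

import numpy as np
import pandas as pd
import pytest

from afmeg import behavior, synthgen


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def error_rate_oracle(events, horizon=5):
    """Exhaustive window scan over a sorted event table."""
    counts = {}
    ev = events.sort_values(["subject", "trial", "keystroke_index"])
    for (subj, _), g in ev.groupby(["subject", "trial"]):
        fb = g["feedback"].to_numpy()
        err = g["is_error"].to_numpy()
        cond = (g["feedback"] + "-" + g["position_class"]).to_numpy()
        n = len(g)
        for j in range(n):
            window = range(j + 1, min(j + 1 + horizon, n))
            if not window:
                continue
            if any(fb[w] == "AF" for w in window):
                continue
            key = (subj, cond[j])
            num, den = counts.get(key, (0, 0))
            counts[key] = (num + int(any(err[w] for w in window)), den + 1)
    return {k: num / den for k, (num, den) in counts.items() if den}


def d_ioi_oracle(events):
    vals = {}
    ev = events.sort_values(["subject", "trial", "keystroke_index"])
    for (subj, _), g in ev.groupby(["subject", "trial"]):
        on = g["onset_ms"].to_numpy()
        cond = (g["feedback"] + "-" + g["position_class"]).to_numpy()
        for j in range(1, len(g) - 1):
            d = (on[j + 1] - on[j]) - (on[j] - on[j - 1])
            vals.setdefault((subj, cond[j]), []).append(d)
    return {k: float(np.mean(v)) for k, v in vals.items()}


# ---------------------------------------------------------------------------


class TestIoi:
    def test_constant_onsets(self, events_factory):
        ev = events_factory([[0, 300, 600, 900]])
        ioi = behavior.compute_ioi(ev)
        assert np.isnan(ioi.iloc[0])
        assert ioi.iloc[1:].tolist() == [300, 300, 300]
        per_trial = behavior.compute_cv_ioi(ev)
        assert per_trial["cv_ioi"].iloc[0] == 0.0

    def test_simple_arithmetic(self, events_factory):
        ev = events_factory([[0, 300, 650]])
        assert behavior.compute_ioi(ev).iloc[1:].tolist() == [300, 350]

    def test_no_cross_trial_interval(self, events_factory):
        ev = events_factory([[0, 300], [0, 400]])
        ioi = behavior.compute_ioi(ev)
        assert np.isnan(ioi.iloc[2])  # first keystroke of trial 2

    def test_non_monotonic_onsets_named(self, events_factory):
        ev = events_factory([[0, 300, 250]])
        with pytest.raises(ValueError, match="trial 1"):
            behavior.compute_ioi(ev)


class TestCvIoi:
    def test_matches_independent_two_pass_computation(self, rng,
                                                      events_factory):
        onsets = np.concatenate([[0.0], np.cumsum(rng.uniform(200, 400, 49))])
        ev = events_factory([onsets.tolist()])
        res = behavior.compute_cv_ioi(ev)
        iois = np.diff(onsets)
        mean = sum(iois) / len(iois)
        sd = np.sqrt(sum((x - mean) ** 2 for x in iois) / (len(iois) - 1))
        assert res["cv_ioi"].iloc[0] == pytest.approx(sd / mean, rel=1e-12)
        assert res["mean_ioi"].iloc[0] == pytest.approx(mean, rel=1e-12)


class TestErrorRate:
    def test_no_errors_gives_zero(self, events_factory):
        fb = ["NF"] * 30
        for k in (5, 15, 25):
            fb[k] = "AF"
        ev = events_factory([np.arange(30) * 300.0], feedback=fb)
        res = behavior.compute_error_rate(ev)
        af = res[res.condition.str.startswith("AF")]
        assert (af["error_rate"] == 0.0).all()

    def test_single_induced_error_rate(self, events_factory):
        # 4 AF events spaced 8 apart, one error 3 after the second AF
        n = 40
        fb = ["NF"] * n
        err = [False] * n
        for k in (4, 12, 20, 28):
            fb[k] = "AF"
        err[15] = True
        ev = events_factory([np.arange(n) * 300.0], feedback=fb, errors=err)
        res = behavior.compute_error_rate(ev)
        af = res[res.condition.str.startswith("AF")]
        assert af["n_events"].sum() == 4
        assert af["n_induced"].sum() == 1

    def test_af_followed_by_af_excluded(self, events_factory):
        n = 30
        fb = ["NF"] * n
        err = [False] * n
        fb[5], fb[9] = "AF", "AF"   # B is 4 keystrokes after A
        err[7] = True               # error at A+2 attributable to either
        ev = events_factory([np.arange(n) * 300.0], feedback=fb, errors=err)
        res = behavior.compute_error_rate(ev)
        af = res[res.condition.str.startswith("AF")]
        # A excluded; only B remains and induces nothing
        assert af["n_events"].sum() == 1
        assert af["n_induced"].sum() == 0

    def test_matches_brute_force_on_random_tables(self, rng, events_factory):
        for _ in range(20):
            n = int(rng.integers(20, 120))
            fb = np.where(rng.random(n) < 0.15, "AF", "NF").tolist()
            err = (rng.random(n) < 0.1).tolist()
            ev = events_factory([np.arange(n) * 300.0], feedback=fb,
                                errors=err)
            res = behavior.compute_error_rate(ev)
            oracle = error_rate_oracle(ev)
            got = {(r.subject, r.condition): r.error_rate
                   for r in res.itertuples() if not np.isnan(r.error_rate)}
            assert got == pytest.approx(oracle)

    def test_rate_invariant_under_trial_reordering(self, small_config):
        ev = synthgen.generate_performance(small_config)
        res_a = behavior.compute_error_rate(ev)
        shuffled = ev.sample(frac=1.0, random_state=0)
        res_b = behavior.compute_error_rate(shuffled)
        pd.testing.assert_frame_equal(res_a.reset_index(drop=True),
                                      res_b.reset_index(drop=True))


class TestPostFeedbackChange:
    def test_explicit_arithmetic(self, events_factory):
        # IOI(event)=350, IOI(+1)=399 at the AF keystroke
        ev = events_factory([[0.0, 350.0, 749.0, 1049.0]],
                            feedback=["NF", "AF", "NF", "NF"])
        res = behavior.compute_post_feedback_change(ev)
        af = res[res.condition.str.startswith("AF")]
        assert af["mean_d_ioi"].iloc[0] == pytest.approx(49.0)

    def test_constant_tempo_gives_zero_everywhere(self, events_factory):
        fb = ["NF"] * 20
        fb[8] = "AF"
        ev = events_factory([np.arange(20) * 300.0], feedback=fb)
        res = behavior.compute_post_feedback_change(ev)
        assert np.allclose(res["mean_d_ioi"], 0.0)

    def test_matches_brute_force_oracle(self, rng, events_factory):
        n = 80
        onsets = np.concatenate([[0.0], np.cumsum(rng.uniform(200, 400,
                                                              n - 1))])
        fb = np.where(rng.random(n) < 0.2, "AF", "NF").tolist()
        ev = events_factory([onsets.tolist()], feedback=fb)
        res = behavior.compute_post_feedback_change(ev)
        oracle = d_ioi_oracle(ev)
        got = {(r.subject, r.condition): r.mean_d_ioi
               for r in res.itertuples()}
        assert got == pytest.approx(oracle)

    def test_recovers_generator_ground_truth(self):
        cfg = synthgen.SimulationConfig(
            n_subjects=10, sequence_patterns=((60, 62, 64, 65),),
            slowing_effect={"Bo": 50.0, "In": 0.0}, ioi_noise_sd=30.0,
            seed=3)
        ev = synthgen.generate_performance(cfg)
        res = behavior.compute_post_feedback_change(ev)
        means = res.groupby("condition")["mean_d_ioi"].mean()
        assert means["AF-Bo"] == pytest.approx(50.0, abs=6.0)
        assert means["AF-In"] == pytest.approx(0.0, abs=6.0)

    def test_invariant_under_time_translation(self, small_config):
        ev = synthgen.generate_performance(small_config)
        res_a = behavior.compute_post_feedback_change(ev)
        ev2 = ev.copy()
        ev2["onset_ms"] += 1234.5  # uniform shift of every trial
        res_b = behavior.compute_post_feedback_change(ev2)
        pd.testing.assert_frame_equal(res_a, res_b)


class TestDetectErrors:
    PATTERNS = {0: (60, 62, 64, 65)}

    def test_perfect_performance_flags_nothing(self, events_factory):
        ev = events_factory([np.arange(16) * 300.0])
        assert not behavior.detect_errors(ev, self.PATTERNS).any()

    def test_single_substitution_flagged_once(self, events_factory):
        ev = events_factory([np.arange(16) * 300.0])
        ev.loc[6, "pitch_played"] = 100
        flags = behavior.detect_errors(ev, self.PATTERNS)
        assert flags.sum() == 1 and flags.loc[6]

    def test_random_corruptions_recovered(self, rng, events_factory):
        ev = events_factory([np.arange(60) * 300.0])
        mask = rng.random(60) < 0.1
        ev.loc[mask, "pitch_played"] = 100  # pitch outside the pattern
        flags = behavior.detect_errors(ev, self.PATTERNS)
        assert np.array_equal(flags.to_numpy(), mask)

    def test_unknown_pattern_rejected(self, events_factory):
        ev = events_factory([np.arange(8) * 300.0])
        with pytest.raises(KeyError, match="pattern"):
            behavior.detect_errors(ev, {5: (60,) * 4})

    def test_generator_injected_errors_recovered(self, small_config):
        # pitches spaced > 2 semitones: a wrong (adjacent-key) pitch can
        # never coincide with another pattern element, so pitch-only
        # detection is unambiguous
        cfg = dataclasses.replace(small_config, baseline_error_prob=0.05,
                                  ioi_noise_sd=0.0,
                                  sequence_patterns=((60, 65, 70, 75),))
        ev = synthgen.generate_performance(cfg)
        flags = behavior.detect_errors(
            ev, dict(enumerate(cfg.sequence_patterns)))
        assert np.array_equal(flags.to_numpy(), ev["is_error"].to_numpy())


class TestLearningCurves:
    def test_stationary_generator_has_no_drift(self, small_config):
        ev = synthgen.generate_performance(small_config)
        pairs = behavior.learning_curves(ev)["pairs"]
        diff = pairs["mean_ioi_second_half"] - pairs["mean_ioi_first_half"]
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean()) < 4 * se + 1e-9

    def test_injected_tempo_drift_recovered(self, small_config, events_factory):
        ev = synthgen.generate_performance(
            dataclasses.replace(small_config, ioi_noise_sd=5.0))
        # slow down the second half of the perturbation-free trials by 21 ms
        nf_trials = sorted(
            set(ev.trial.unique()) -
            set(ev.loc[ev.feedback == "AF", "trial"].unique()))
        late = nf_trials[len(nf_trials) // 2:]
        sel = ev.trial.isin(late)
        ev.loc[sel, "onset_ms"] += ev.loc[sel, "keystroke_index"] * 21.0
        pairs = behavior.learning_curves(ev)["pairs"]
        diff = (pairs["mean_ioi_second_half"] -
                pairs["mean_ioi_first_half"]).mean()
        assert diff == pytest.approx(21.0, abs=3.0)

    def test_single_nf_trial_rejected(self, events_factory):
        fb1 = ["NF"] * 10
        fb2 = ["NF"] * 10
        fb2[4] = "AF"
        ev = events_factory([np.arange(10) * 300.0, np.arange(10) * 300.0],
                            feedback=fb1 + fb2)
        with pytest.raises(ValueError, match="fewer than 2"):
            behavior.learning_curves(ev)


class TestFactorialCells:
    def test_missing_cell_detected(self, small_config):
        ev = synthgen.generate_performance(small_config)
        table = behavior.compute_post_feedback_change(ev)
        cells, subjects = behavior.factorial_cells(table, "mean_d_ioi")
        assert cells.shape == (small_config.n_subjects, 2, 2)
        with pytest.raises(ValueError, match="missing"):
            behavior.factorial_cells(table.iloc[:-1], "mean_d_ioi")
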