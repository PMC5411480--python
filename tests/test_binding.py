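import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats

import tonebind as tb
from tonebind.binding import shift_percept


@given(mus=hst.lists(hst.floats(10.0, 150.0), min_size=1, max_size=6),
       tones=hst.lists(hst.floats(10.0, 150.0), min_size=1, max_size=8),
       belief_var=hst.floats(0.05, 5.0),
       noise_var=hst.floats(0.0, 3.0))
@settings(derandomize=True, max_examples=60, deadline=None)
def test_responsibilities_always_normalize(mus, tones, belief_var, noise_var):
    """Each tone is fully distributed over tracks for any track layout,
    belief variance and sensory-noise level."""
    params = tb.ModelParams(1.0, 0.0)
    tracks = [tb.TrackBelief(m, belief_var, i) for i, m in enumerate(mus)]
    sensed = tb.SensedChord(np.array(tones), noise_var,
                            tb.Chord((440.0,), 125.0))
    att = tb.attribute(tracks, sensed, params)
    assert np.allclose(att.responsibilities.sum(axis=0), 1.0, atol=1e-9)
    assert att.effective_counts.sum() == pytest.approx(len(tones))


def single_tone_trial(f1_hz, f2_hz, context_hz=None, duration_ms=125.0):
    """Minimal trial made of single-component chords."""
    chords = []
    t = 0.0
    bias = "none"
    if context_hz is not None:
        chords.append(tb.Chord((context_hz,), duration_ms, t, "context"))
        t += 2 * duration_ms
        bias = "up" if context_hz > f1_hz else "down"
    chords.append(tb.Chord((f1_hz,), duration_ms, t, "test1"))
    chords.append(tb.Chord((f2_hz,), duration_ms, t + 2 * duration_ms,
                           "test2"))
    return tb.TrialSpec(0, "exp1", {}, chords, bias, 0)


class TestSense:
    def test_noiseless_limit_is_exact(self, rng):
        chord = tb.make_shepard_tone(70.0)
        sensed = tb.sense(chord, tb.ModelParams(1.0, 0.0), rng)
        assert np.array_equal(sensed.g, chord.log_components)
        assert sensed.noise_variance == 0.0

    @pytest.mark.parametrize("duration,expected_var", [
        (150.0, 1.0), (300.0, 0.5), (75.0, 2.0)])
    def test_noise_variance_scales_inversely_with_duration(
            self, rng, duration, expected_var):
        chord = tb.Chord((440.0,), duration)
        sensed = tb.sense(chord, tb.ModelParams(1.0, 1.0), rng)
        assert sensed.noise_variance == pytest.approx(expected_var)

    def test_noise_statistics(self):
        chord = tb.Chord((440.0,), 150.0)
        params = tb.ModelParams(1.0, 2.0)
        rng = np.random.default_rng(1)
        draws = np.array([tb.sense(chord, params, rng).g[0]
                          for _ in range(4000)])
        assert draws.mean() == pytest.approx(chord.log_components[0], abs=0.1)
        assert draws.var() == pytest.approx(2.0, rel=0.1)


class TestInitialization:
    def test_one_track_per_component(self, rng, params):
        chord = tb.make_shepard_tone(60.0)
        tracks = tb.initialize_tracks(tb.sense(chord, params, rng), params)
        assert len(tracks) == 9

    def test_variance_is_track_plus_sensory(self, rng):
        chord = tb.Chord((440.0,), 150.0)
        params = tb.ModelParams(2.0, 1.0)
        tracks = tb.initialize_tracks(tb.sense(chord, params, rng), params)
        assert tracks[0].var == pytest.approx(3.0)
        noiseless = tb.ModelParams(2.0, 0.0)
        tracks = tb.initialize_tracks(tb.sense(chord, noiseless, rng),
                                      noiseless)
        assert tracks[0].var == pytest.approx(2.0)

    def test_coincident_components_allowed(self, rng):
        chord = tb.Chord((440.0, 440.0), 125.0)
        params = tb.ModelParams(1.0, 0.0)
        tracks = tb.initialize_tracks(tb.sense(chord, params, rng), params)
        assert len(tracks) == 2
        assert tracks[0].mu == tracks[1].mu


class TestAttribution:
    def test_single_track_takes_everything(self, rng):
        params = tb.ModelParams(1.0, 0.0)
        chord = tb.make_shepard_tone(60.0)
        sensed = tb.sense(chord, params, rng)
        tracks = [tb.TrackBelief(50.0, 1.0, 0)]
        att = tb.attribute(tracks, sensed, params)
        assert np.allclose(att.responsibilities, 1.0)

    def test_midway_tone_splits_evenly(self):
        params = tb.ModelParams(1.0, 0.0)
        tracks = [tb.TrackBelief(0.0, 1.0, 0), tb.TrackBelief(6.0, 1.0, 1)]
        sensed = tb.SensedChord(np.array([3.0]), 0.0,
                                tb.Chord((440.0,), 125.0))
        att = tb.attribute(tracks, sensed, params)
        assert np.allclose(att.responsibilities[:, 0], [0.5, 0.5])

    def test_against_direct_density_oracle(self):
        # tracks at 0 and 6 st (belief var 1 each), sigma2_track = 1,
        # no sensory noise, tone at 2 st
        params = tb.ModelParams(1.0, 0.0)
        tracks = [tb.TrackBelief(0.0, 1.0, 0), tb.TrackBelief(6.0, 1.0, 1)]
        sensed = tb.SensedChord(np.array([2.0]), 0.0,
                                tb.Chord((440.0,), 125.0))
        att = tb.attribute(tracks, sensed, params)
        # oracle: normalized predictive densities, variance = 1 + 1 + 0
        d0 = stats.norm.pdf(2.0, loc=0.0, scale=np.sqrt(2.0))
        d1 = stats.norm.pdf(2.0, loc=6.0, scale=np.sqrt(2.0))
        assert att.responsibilities[0, 0] == pytest.approx(d0 / (d0 + d1),
                                                           abs=1e-12)
        assert att.effective_counts.sum() == pytest.approx(1.0)

    def test_columns_sum_to_one_property(self, rng):
        params = tb.ModelParams(0.7, 0.4)
        for _ in range(25):
            k = rng.integers(1, 8)
            tracks = [tb.TrackBelief(float(m), float(v), i) for i, (m, v) in
                      enumerate(zip(rng.uniform(20, 140, k),
                                    rng.uniform(0.1, 5.0, k)))]
            g = rng.uniform(20, 140, rng.integers(1, 10))
            sensed = tb.SensedChord(g, 0.6, tb.Chord((440.0,), 125.0))
            att = tb.attribute(tracks, sensed, params)
            assert np.allclose(att.responsibilities.sum(axis=0), 1.0,
                               atol=1e-9)

    def test_zero_count_flagged_undefined(self):
        # a track 200 st away gets essentially zero responsibility; with a
        # competing near track the count underflows to exactly 0
        params = tb.ModelParams(1.0, 0.0)
        tracks = [tb.TrackBelief(40.0, 1.0, 0), tb.TrackBelief(240.0, 1.0, 1)]
        sensed = tb.SensedChord(np.array([40.0]), 0.0,
                                tb.Chord((440.0,), 125.0))
        att = tb.attribute(tracks, sensed, params)
        assert not att.defined[1]
        assert np.isnan(att.weighted_means[1])


class TestBeliefUpdate:
    def test_zero_count_leaves_track_unchanged(self):
        params = tb.ModelParams(1.0, 0.0)
        tracks = [tb.TrackBelief(40.0, 1.0, 0), tb.TrackBelief(240.0, 2.5, 1)]
        sensed = tb.SensedChord(np.array([40.0]), 0.0,
                                tb.Chord((440.0,), 125.0))
        att = tb.attribute(tracks, sensed, params)
        new = tb.update_beliefs(tracks, att, sensed, params)
        assert new[1].mu == pytest.approx(240.0)
        assert new[1].var == pytest.approx(2.5)

    def test_conjugate_arithmetic_against_integration_oracle(self):
        # prior N(0, 1), one fully attributed tone at g = 2 with observation
        # variance 1 -> posterior N(1, 0.5)
        params = tb.ModelParams(1.0, 0.0)
        tracks = [tb.TrackBelief(0.0, 1.0, 0)]
        sensed = tb.SensedChord(np.array([2.0]), 0.0,
                                tb.Chord((440.0,), 125.0))
        att = tb.attribute(tracks, sensed, params)
        new = tb.update_beliefs(tracks, att, sensed, params)
        assert new[0].mu == pytest.approx(1.0)
        assert new[0].var == pytest.approx(0.5)
        # numerical-integration oracle for the posterior mean
        mu_grid = np.linspace(-10, 10, 20001)
        post = stats.norm.pdf(mu_grid, 0, 1) * stats.norm.pdf(2.0, mu_grid, 1)
        post /= np.trapezoid(post, mu_grid)
        assert np.trapezoid(mu_grid * post, mu_grid) == pytest.approx(
            new[0].mu, abs=1e-6)

    def test_flat_prior_limit_recovers_weighted_mean(self):
        params = tb.ModelParams(1.0, 0.0)
        tracks = [tb.TrackBelief(0.0, 1e12, 0)]
        sensed = tb.SensedChord(np.array([7.0]), 0.0,
                                tb.Chord((440.0,), 125.0))
        att = tb.attribute(tracks, sensed, params)
        new = tb.update_beliefs(tracks, att, sensed, params)
        assert new[0].mu == pytest.approx(7.0, abs=1e-6)

    def test_posterior_variance_strictly_decreases(self, rng):
        params = tb.ModelParams(1.5, 0.8)
        chord = tb.make_shepard_tone(75.0)
        sensed = tb.sense(chord, params, rng)
        tracks = tb.initialize_tracks(sensed, params)
        for _ in range(5):
            nxt = tb.sense(tb.make_shepard_tone(80.0), params, rng)
            att = tb.attribute(tracks, nxt, params)
            new = tb.update_beliefs(tracks, att, nxt, params)
            for old_t, new_t, n in zip(tracks, new, att.effective_counts):
                if n > 0:
                    assert new_t.var < old_t.var
            tracks = new


class TestProcessTrial:
    def test_unambiguous_single_track_shift(self, rng):
        params = tb.ModelParams(1.0, 0.0)
        f1 = 440.0
        f2 = float(tb.st_to_hz(tb.hz_to_st(440.0) + 1.0))
        percept = tb.process_trial(single_tone_trial(f1, f2), params, rng)
        assert percept.Phi == pytest.approx(1.0)
        assert percept.response == "up"

    def test_ambiguous_tritone_is_tie_without_noise(self):
        # base range restricted so T1 carries 9 components and T2 8: the
        # up and down binding paths then cancel (edge slices where the
        # component counts unbalance the chords are excluded)
        params = tb.ModelParams(2.0, 0.0)
        trials = tb.build_experiment(
            "exp1", dict(intervals_st=(6,), reps=40, n_intertrial=0,
                         fb_range_hz=(62.0, 84.0)), seed=8)
        phis = [tb.process_trial(t, params, np.random.default_rng(0)).Phi
                for t in trials]
        assert np.allclose(phis, 0.0, atol=1e-9)

    def test_exact_tie_broken_by_fair_coin(self):
        # a T2 tone exactly midway between two T1 tracks yields Phi = 0;
        # only the seeded coin decides the report
        r1, g1 = np.eye(2), np.array([0.0, 12.0])
        r2, g2 = np.array([[0.5], [0.5]]), np.array([6.0])
        percepts = [shift_percept(r1, g1, r2, g2, np.random.default_rng(i))
                    for i in range(100)]
        assert all(p.Phi == 0.0 for p in percepts)
        n_up = sum(p.response == "up" for p in percepts)
        assert 20 <= n_up <= 80

    def test_context_biases_toward_its_region(self, rng):
        """A single context tone halfway between T1 and T2 pulls the percept
        through its own frequency region (3-octave reduced stimulus)."""
        params = tb.ModelParams(2.0, 0.0)
        st1 = tb.hz_to_st(220.0)
        mk = lambda offsets, onset, role: tb.Chord(
            tuple(float(tb.st_to_hz(st1 + o)) for o in offsets),
            125.0, onset, role)
        t1 = mk([0, 12, 24], 250.0, "test1")
        t2 = mk([6, 18, 30], 500.0, "test2")
        ctx = mk([3, 15, 27], 0.0, "context")
        trial = tb.TrialSpec(0, "exp2", {}, [ctx, t1, t2], "up", 0)
        percept = tb.process_trial(trial, params, rng)
        assert percept.Phi > 0
        assert percept.response == "up"
        # independent exhaustive-pairing oracle (explicit double loop,
        # densities straight from scipy)
        assert percept.Phi == pytest.approx(
            exhaustive_phi([ctx, t1, t2], params), rel=1e-9)

    def test_missing_test_chord_rejected(self, rng, params):
        c1 = tb.Chord((440.0,), 125.0, 0.0, "test1")
        c2 = tb.Chord((466.0,), 125.0, 250.0, "test2")
        trial = tb.TrialSpec(0, "exp1", {}, [c1, c2], "none", 0)
        trial.chords = [c1]  # corrupt after construction
        with pytest.raises(ValueError):
            tb.process_trial(trial, params, rng)

    def test_batched_path_matches_sequential_noiseless(self):
        params = tb.ModelParams(2.0, 0.0)
        trials = tb.build_experiment("exp2", dict(reps=4), seed=13)
        trials = [t for t in trials if t.condition["n_context"] > 0]
        batched = tb.simulate_trials(trials, params,
                                     np.random.default_rng(0), 1)[0]
        sequential = [tb.process_trial(t, params,
                                       np.random.default_rng(0)).response
                      == "up" for t in trials]
        assert list(batched) == sequential


class TestMeanFieldVersusExhaustive:
    """Mean-field posterior means vs exact enumeration over all hard
    assignments, for 2 tracks x 2 tones."""

    @staticmethod
    def exact_posterior_means(mu, var, g, obs_var):
        weights, means = [], []
        for assign in itertools.product([0, 1], repeat=2):
            w = np.prod([stats.norm.pdf(g[j], mu[assign[j]],
                                        np.sqrt(var[assign[j]] + obs_var))
                         for j in range(2)])
            post = np.array(mu, dtype=float)
            post_var = np.array(var, dtype=float)
            for i in (0, 1):
                assigned = [g[j] for j in range(2) if assign[j] == i]
                prec = 1 / post_var[i] + len(assigned) / obs_var
                post[i] = (mu[i] / var[i]
                           + np.sum(assigned) / obs_var) / prec
                post_var[i] = 1 / prec
            weights.append(w)
            means.append(post)
        weights = np.array(weights) / np.sum(weights)
        return (weights[:, None] * np.array(means)).sum(axis=0)

    def test_agreement_for_separated_tracks(self):
        rng = np.random.default_rng(42)
        params = tb.ModelParams(1.0, 0.0)
        for _ in range(30):
            sep = rng.uniform(4.0, 12.0)
            mu = np.array([60.0, 60.0 + sep])
            var = rng.uniform(0.3, 1.5, 2)
            g = mu + rng.normal(0, 0.8, 2)
            obs_var = params.sigma2_track  # noiseless chord
            tracks = [tb.TrackBelief(mu[i], var[i], i) for i in range(2)]
            sensed = tb.SensedChord(g, 0.0, tb.Chord((440.0, 550.0), 125.0))
            att = tb.attribute(tracks, sensed, params)
            new = tb.update_beliefs(tracks, att, sensed, params)
            exact = self.exact_posterior_means(mu, var, g, obs_var)
            mf = np.array([t.mu for t in new])
            assert np.all(np.abs(mf - exact) <= 0.05 * sep)


class TestPredictCondition:
    def test_deterministic_given_seed(self, params):
        trials = tb.build_experiment("exp2", dict(reps=3), seed=14)
        a = tb.predict_condition(trials, params, n_sim=5)
        b = tb.predict_condition(trials, params, n_sim=5)
        assert a.equals(b)

    def test_lapse_pulls_probabilities_to_half(self):
        trials = tb.build_experiment(
            "exp1", dict(intervals_st=(1,), reps=20), seed=15)
        sure = tb.ModelParams(2.0, 0.01)
        lapsy = tb.ModelParams(2.0, 0.01, lapse=0.4)
        p_sure = tb.predict_condition(trials, sure, n_sim=5).p_response[0]
        p_lapsy = tb.predict_condition(trials, lapsy, n_sim=5).p_response[0]
        assert p_sure >= 0.9
        assert abs(p_lapsy - 0.5) < abs(p_sure - 0.5)

    def test_empty_condition_rejected(self, params):
        with pytest.raises(ValueError):
            tb.predict_condition([], params)


def exhaustive_phi(chords, params):
    """Independent re-derivation of the trial percept: sequential soft
    assignment with scipy densities and explicit pair sums."""
    mu = np.array(chords[0].log_components, dtype=float)
    var = np.full_like(mu, params.sigma2_track)  # noiseless: var0 = s2t
    r_list, g_list = [], []
    for chord in chords[1:]:
        g = chord.log_components
        r = np.zeros((len(mu), len(g)))
        for j, gj in enumerate(g):
            dens = np.array([stats.norm.pdf(
                gj, mu[i], np.sqrt(var[i] + params.sigma2_track))
                for i in range(len(mu))])
            r[:, j] = dens / dens.sum()
        r_list.append(r)
        g_list.append(g)
        for i in range(len(mu)):
            n_i = r[i].sum()
            if n_i > 0:
                gbar = (r[i] * g).sum() / n_i
                prec = 1 / var[i] + n_i / params.sigma2_track
                mu[i] = (mu[i] / var[i]
                         + n_i * gbar / params.sigma2_track) / prec
                var[i] = 1 / prec
    (r1, r2), (g1, g2) = r_list[-2:], g_list[-2:]
    phi = 0.0
    for i in range(len(mu)):
        for j in range(len(g1)):
            for k in range(len(g2)):
                phi += r1[i, j] * r2[i, k] * (g2[k] - g1[j])
    return phi
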