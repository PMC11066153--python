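"""Decoder checks against hand counts and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tiltbmi import synth, decoder
from conftest import make_session, tuned_specs, flat_trajectory


# --- independent oracles -------------------------------------------------

def brute_force_classify(trial_counts, template_set):
    """Explicit-loop nearest-template search (independent of classify_trial)."""
    best_tilt, best_dist = None, None
    for tilt in (1, 2, 3, 4):
        tmpl = template_set.templates[tilt].values
        total = 0.0
        for n in range(trial_counts.shape[0]):
            for b in range(trial_counts.shape[1]):
                total += (trial_counts[n, b] - tmpl[n, b]) ** 2
        dist = total ** 0.5
        if best_dist is None or dist < best_dist:
            best_tilt, best_dist = tilt, dist
    return best_tilt


def brute_force_loo(counts, labels):
    """Naive leave-one-out nearest-template predictions via explicit loops."""
    n = len(labels)
    preds = []
    for i in range(n):
        dists = []
        for tilt in (1, 2, 3, 4):
            members = [j for j in range(n) if j != i and labels[j] == tilt]
            tmpl = counts[members].mean(axis=0)
            dists.append(np.sqrt(((counts[i] - tmpl) ** 2).sum()))
        preds.append(int(np.argmin(dists)) + 1)
    return np.array(preds)


def _templates_from_arrays(arrays, bin_edges, neuron_ids):
    return decoder.TemplateSet(
        day=0,
        templates={
            t: decoder.PsthMatrix(
                tilt_type=t, neuron_ids=neuron_ids, bin_edges=bin_edges,
                values=arrays[t - 1], n_trials=1,
            )
            for t in (1, 2, 3, 4)
        },
        neuron_ids=neuron_ids,
    )


# --- PSTH construction ---------------------------------------------------

class TestBuildPsth:
    def test_single_spike_every_trial(self):
        spikes = [("n0", t, 10.0) for t in range(100)]
        rec = make_session([1] * 100, spikes)
        # need trials of every tilt type for build_psth; restrict to a
        # session with all four, one spike only on tilt-1 trials
        rec = make_session([1, 2, 3, 4] * 25, [("n0", t, 10.0) for t in range(0, 100, 4)])
        psths = decoder.build_psth(rec)
        vals = psths[1].values[0]
        bin_idx = int((0.0 - -200.0) / 20.0)  # bin [0, 20)
        assert vals[bin_idx] == 1.0
        assert vals.sum() == 1.0
        assert psths[2].values.sum() == 0.0

    def test_no_spikes_gives_zero_psth(self):
        rec = make_session([1, 2, 3, 4], [], neurons=[("n0", "direct")])
        psths = decoder.build_psth(rec)
        for t in (1, 2, 3, 4):
            assert psths[t].values.sum() == 0.0

    def test_hand_counted_two_trial_psth(self):
        """Trials with spikes {-5} and {-5, +30}: bin [-20,0)=1.0, [20,40)=0.5."""
        spikes = [("n0", 0, -5.0), ("n0", 1, -5.0), ("n0", 1, 30.0)]
        rec = make_session([1, 1, 2, 3, 4], spikes + [("n0", i, 0.0) for i in (2, 3, 4)])
        psths = decoder.build_psth(rec, trial_ids=None)
        v = psths[1].values[0]
        edges = psths[1].bin_edges
        assert v[np.searchsorted(edges, -20.0)] == 1.0
        assert v[np.searchsorted(edges, 20.0)] == 0.5

    def test_spike_at_right_edge_excluded(self):
        rec = make_session([1, 2, 3, 4], [("n0", 0, 200.0), ("n0", 0, 199.9)])
        psths = decoder.build_psth(rec)
        assert psths[1].values.sum() == 1.0  # only the 199.9 ms spike counts

    def test_missing_tilt_type_raises(self):
        rec = make_session([1, 1, 2, 3], [("n0", 0, 0.0)])
        with pytest.raises(decoder.DegenerateInputError):
            decoder.build_psth(rec)


# --- single-trial classification ----------------------------------------

class TestClassifyTrial:
    edges = np.array([0.0, 20.0, 40.0])

    def test_exact_template_match_distance_zero(self):
        arrays = [np.array([[1.0, 0.0]]), np.array([[0.0, 2.0]]),
                  np.array([[3.0, 0.0]]), np.array([[0.0, 4.0]])]
        ts = _templates_from_arrays(arrays, self.edges, ("n0",))
        pred, dists = decoder.classify_trial(np.array([[0.0, 2.0]]), ts)
        assert pred == 2 and dists[2] == 0.0

    def test_all_templates_identical_ties_to_lowest_tilt(self):
        arrays = [np.array([[1.0, 1.0]])] * 4
        ts = _templates_from_arrays(arrays, self.edges, ("n0",))
        pred, dists = decoder.classify_trial(np.array([[5.0, 5.0]]), ts)
        assert pred == 1
        assert len(set(dists.values())) == 1

    def test_two_neuron_toy_tie_break(self):
        """Trial (1,0,0,1) vs T1=(1,0,0,0), T2=(0,0,0,1): both at distance 1."""
        arrays = [
            np.array([[1.0, 0.0], [0.0, 0.0]]),
            np.array([[0.0, 0.0], [0.0, 1.0]]),
            np.array([[9.0, 9.0], [9.0, 9.0]]),
            np.array([[8.0, 8.0], [8.0, 8.0]]),
        ]
        ts = _templates_from_arrays(arrays, self.edges, ("n0", "n1"))
        trial = np.array([[1.0, 0.0], [0.0, 1.0]])
        pred, dists = decoder.classify_trial(trial, ts)
        assert dists[1] == pytest.approx(1.0) and dists[2] == pytest.approx(1.0)
        assert pred == 1
        assert pred == brute_force_classify(trial, ts)

    def test_roster_mismatch_raises(self):
        arrays = [np.zeros((1, 2))] * 4
        ts = _templates_from_arrays(arrays, self.edges, ("n0",))
        with pytest.raises(decoder.RosterError):
            decoder.classify_trial(np.zeros((2, 2)), ts)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_neurons, n_bins = int(rng.integers(1, 5)), int(rng.integers(1, 6))
        edges = 20.0 * np.arange(n_bins + 1)
        arrays = [rng.poisson(2.0, (n_neurons, n_bins)).astype(float) for _ in range(4)]
        ts = _templates_from_arrays(arrays, edges, tuple(f"n{i}" for i in range(n_neurons)))
        trial = rng.poisson(2.0, (n_neurons, n_bins)).astype(float)
        pred, _ = decoder.classify_trial(trial, ts)
        assert pred == brute_force_classify(trial, ts)


# --- leave-one-out offline decoding --------------------------------------

class TestDecodeOffline:
    def test_perfectly_tuned_neurons_decode_perfectly(self, strongly_tuned_session):
        cm, acc = decoder.decode_offline(strongly_tuned_session)
        assert acc == 1.0
        assert np.trace(cm) == strongly_tuned_session.n_trials

    def test_untuned_session_at_chance(self, untuned_session):
        _, acc = decoder.decode_offline(untuned_session)
        # binomial 99.9% CI around 0.25 at 400 trials
        assert abs(acc - 0.25) < 3.3 * np.sqrt(0.25 * 0.75 / 400)

    def test_loo_matches_brute_force_trace_on_toy_session(self):
        """8 hand-built trials: vectorized LOO equals the explicit-loop oracle."""
        tilts = [1, 1, 2, 2, 3, 3, 4, 4]
        spikes = [
            ("n0", 0, 10.0), ("n0", 1, 12.0),
            ("n0", 2, 110.0), ("n0", 3, 112.0), ("n0", 3, 115.0),
            ("n1", 4, -50.0), ("n1", 5, -52.0),
            ("n1", 6, 150.0), ("n0", 7, 150.0), ("n1", 7, 155.0),
        ]
        rec = make_session(tilts, spikes, neurons=[("n0", "direct"), ("n1", "direct")])
        cm, acc = decoder.decode_offline(rec)
        edges = decoder.make_bin_edges(20.0, (-200.0, 200.0))
        counts = decoder.bin_spike_counts(rec, ["n0", "n1"], edges, rec.trials["trial_id"].to_numpy())
        flat = counts.reshape(8, -1)
        oracle_preds = brute_force_loo(flat, np.array(tilts))
        oracle_cm = decoder.confusion_matrix(np.array(tilts), oracle_preds)
        assert np.array_equal(cm, oracle_cm)
        assert acc == (oracle_preds == np.array(tilts)).mean()

    def test_first_n_filter_limits_trials(self, untuned_session):
        cm, _ = decoder.decode_offline(untuned_session, first_n=300)
        assert cm.sum() == 300

    def test_too_few_trials_per_type_raises(self):
        rec = make_session([1, 2, 3, 4], [("n0", 0, 0.0)])
        with pytest.raises(decoder.DegenerateInputError):
            decoder.decode_offline(rec)

    def test_accuracy_invariant_to_neuron_relabeling(self, strongly_tuned_session):
        rec = strongly_tuned_session
        renamed = synth.SessionRecording(
            animal_id=rec.animal_id,
            day=rec.day,
            trials=rec.trials.copy(),
            spikes=rec.spikes.assign(neuron_id=rec.spikes["neuron_id"].map(lambda s: "x" + s)),
            neurons=rec.neurons.assign(neuron_id=rec.neurons["neuron_id"].map(lambda s: "x" + s)),
        )
        _, acc1 = decoder.decode_offline(rec)
        _, acc2 = decoder.decode_offline(renamed)
        assert acc1 == acc2


# --- online decoding and roster rules ------------------------------------

class TestOnlineDecoding:
    def test_online_close_to_offline_for_stationary_data(self):
        amps = [(50.0, 0.0, 0.0, 0.0), (0.0, 50.0, 0.0, 0.0),
                (0.0, 0.0, 50.0, 0.0), (0.0, 0.0, 0.0, 50.0)]
        specs = tuned_specs(amps, background=4.0)
        traj = flat_trajectory(2)
        yesterday = synth.simulate_session(specs, 0, traj, 400, seed=31)
        today = synth.simulate_session(specs, 1, traj, 400, seed=32)
        _, on_out = decoder.decode_online(today, yesterday)
        on_acc = (on_out["outcome"] == "correct").mean()
        _, off_acc = decoder.decode_offline(today)
        assert abs(on_acc - off_acc) < 0.1

    def test_online_deterministic(self):
        specs = tuned_specs([(30.0, 0.0, 0.0, 0.0)])
        traj = flat_trajectory(2)
        y = synth.simulate_session(specs, 0, traj, 40, seed=1)
        t = synth.simulate_session(specs, 1, traj, 40, seed=2)
        cm1, o1 = decoder.decode_online(t, y)
        cm2, o2 = decoder.decode_online(t, y)
        assert np.array_equal(cm1, cm2)
        assert (o1["predicted"] == o2["predicted"]).all()

    def test_silent_yesterday_roster_raises(self):
        y = make_session([1, 2, 3, 4], [], neurons=[("n0", "direct")])
        t = make_session([1, 2, 3, 4], [("n0", 0, 5.0)], neurons=[("n0", "direct")])
        with pytest.raises(decoder.RosterError):
            decoder.decode_online(t, y)

    def test_reconcile_roster_intersection_rule(self):
        """Yesterday {a,b,c}, today {b,c,d} -> decode with {b,c}; d waits a day."""
        y = make_session(
            [1, 2, 3, 4],
            [("a", 0, 1.0), ("b", 1, 1.0), ("c", 2, 1.0)],
            neurons=[(n, "direct") for n in "abc"],
        )
        t = make_session(
            [1, 2, 3, 4],
            [("b", 0, 1.0), ("c", 1, 1.0), ("d", 2, 1.0)],
            neurons=[(n, "direct") for n in "bcd"],
        )
        assert decoder.reconcile_roster(y, t) == ["b", "c"]
        # identical rosters pass through unchanged
        assert decoder.reconcile_roster(y, y) == ["a", "b", "c"]
        # disjoint rosters -> empty
        z = make_session([1, 2, 3, 4], [("e", 0, 1.0)], neurons=[("e", "direct")])
        assert decoder.reconcile_roster(y, z) == []


class TestMonotonicRecovery:
    def test_offline_accuracy_monotone_in_amplitude_separation(self):
        """Accuracy rises with tilt-type amplitude separation (Spearman > 0.9)."""
        from scipy.stats import spearmanr

        levels = [0.0, 12.0, 24.0, 36.0, 48.0]
        mean_acc = []
        for sep in levels:
            accs = []
            for seed in range(3):
                amps = [
                    (20.0 + sep, 20.0, 20.0, 20.0),
                    (20.0, 20.0 + sep, 20.0, 20.0),
                ]
                specs = tuned_specs(amps, background=5.0)
                rec = synth.simulate_session(specs, 0, flat_trajectory(), 200, seed=100 + seed)
                accs.append(decoder.decode_offline(rec)[1])
            mean_acc.append(np.mean(accs))
        rho = spearmanr(levels, mean_acc).statistic
        assert rho > 0.9
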