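"""Information measures: closed forms, shuffle bias, redundancy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tiltbmi import synth, info, decoder
from conftest import make_session, tuned_specs, flat_trajectory


def mi_oracle(cm):
    """Term-by-term plug-in mutual information, independent implementation."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    mi = 0.0
    for r in range(cm.shape[0]):
        for s in range(cm.shape[1]):
            p_rs = cm[r, s] / total
            if p_rs == 0:
                continue
            p_r = cm[r, :].sum() / total
            p_s = cm[:, s].sum() / total
            mi += p_rs * np.log2(p_rs / (p_r * p_s))
    return mi


class TestMutualInformation:
    def test_perfect_diagonal_gives_two_bits(self):
        assert info.mutual_information(np.eye(4) * 100) == pytest.approx(2.0, abs=1e-12)

    def test_uniform_matrix_gives_zero_bits(self):
        assert info.mutual_information(np.full((4, 4), 25)) == pytest.approx(0.0, abs=1e-12)

    def test_padded_two_class_matrix_matches_oracle(self):
        cm = np.zeros((4, 4))
        cm[0, 0], cm[0, 1], cm[1, 0], cm[1, 1] = 30, 10, 10, 30
        assert info.mutual_information(cm) == pytest.approx(mi_oracle(cm), abs=1e-12)

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            info.mutual_information(np.zeros((4, 4)))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 50, (4, 4))
        if cm.sum() == 0:
            cm[0, 0] = 1
        mi = info.mutual_information(cm)
        assert -1e-12 <= mi <= 2.0 + 1e-12
        assert mi == pytest.approx(mi_oracle(cm), abs=1e-10)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.permutations([0, 1, 2, 3]), st.integers(0, 2**31 - 1))
    def test_invariant_under_simultaneous_row_column_permutation(self, perm, seed):
        rng = np.random.default_rng(seed)
        cm = rng.integers(1, 40, (4, 4))
        permuted = cm[np.ix_(perm, perm)]
        assert info.mutual_information(permuted) == pytest.approx(
            info.mutual_information(cm), abs=1e-12
        )


class TestBiasCorrection:
    def test_untuned_responses_correct_to_near_zero(self):
        """Label shuffling removes nothing when responses carry no tilt signal."""
        specs = tuned_specs([(0.0,) * 4], background=10.0)
        vals, biases = [], []
        for seed in range(6):
            rec = synth.simulate_session(specs, 0, flat_trajectory(), 400, seed=900 + seed)
            resp, labels = info._neuron_responses(rec, ["t00"], 20.0, None)
            est = info.bias_corrected_information(resp, labels, n_shuffles=20, seed=seed)
            vals.append(est.corrected_info)
            biases.append(est.bias)
        assert abs(np.mean(vals)) < 0.02  # ~3 SEM of the corrected estimate
        assert all(b >= 0 for b in biases)

    def test_separable_responses_near_ceiling(self, strongly_tuned_session):
        edges = decoder.make_bin_edges(20.0, (0.0, 200.0))
        roster = strongly_tuned_session.roster()
        counts = decoder.bin_spike_counts(
            strongly_tuned_session, roster, edges,
            strongly_tuned_session.trials["trial_id"].to_numpy(),
        )
        flat = counts.reshape(strongly_tuned_session.n_trials, -1)
        labels = strongly_tuned_session.trials["tilt_type"].to_numpy()
        est = info.bias_corrected_information(flat, labels, n_shuffles=20, seed=1)
        assert est.raw_info == pytest.approx(2.0, abs=0.05)
        assert est.bias > 0
        assert est.corrected_info == pytest.approx(2.0 - est.bias, abs=1e-12)

    def test_single_shuffle_reproducible(self, untuned_session):
        resp, labels = info._neuron_responses(untuned_session, ["t00"], 20.0, 300)
        a = info.bias_corrected_information(resp, labels, n_shuffles=1, seed=42)
        b = info.bias_corrected_information(resp, labels, n_shuffles=1, seed=42)
        assert a.bias == b.bias and a.corrected_info == b.corrected_info

    def test_class_with_too_few_trials_raises(self):
        rec = make_session([1, 1, 2, 2, 3, 3, 4], [("n0", 0, 5.0)])
        resp, labels = info._neuron_responses(rec, ["n0"], 200.0, None)
        with pytest.raises(decoder.DegenerateInputError):
            info.bias_corrected_information(resp, labels, n_shuffles=1, seed=0)


class TestTimingVsCount:
    def test_rate_tuned_neuron_timing_close_to_count(self):
        """Same latency, different amplitudes: timing adds nothing over count."""
        specs = tuned_specs(
            [(60.0, 25.0, 5.0, 0.0)], latencies_by_neuron=[(80.0,) * 4],
            background=3.0, jitter=3.0,
        )
        diffs = []
        for seed in range(4):
            rec = synth.simulate_session(specs, 0, flat_trajectory(), 300, seed=200 + seed)
            timing, count = info.timing_and_count_information(
                rec, "t00", first_n=None, n_shuffles=20, seed=seed
            )
            diffs.append(timing.corrected_info - count.corrected_info)
        assert abs(np.mean(diffs)) < 0.1

    def test_latency_tuned_neuron_has_timing_but_no_count_information(self):
        """Equal counts at distinct latencies: only spike timing is informative."""
        specs = tuned_specs(
            [(60.0,) * 4], latencies_by_neuron=[(20.0, 70.0, 120.0, 170.0)],
            background=2.0, jitter=3.0, width=8.0,
        )
        timings, counts = [], []
        for seed in range(4):
            rec = synth.simulate_session(specs, 0, flat_trajectory(), 300, seed=300 + seed)
            timing, count = info.timing_and_count_information(
                rec, "t00", first_n=None, n_shuffles=20, seed=seed
            )
            timings.append(timing.corrected_info)
            counts.append(count.corrected_info)
        assert np.mean(timings) > 0.3
        assert abs(np.mean(counts)) < 0.05

    def test_silent_neuron_carries_exactly_no_information(self):
        """All-zero responses tie every template: constant prediction, 0 bits."""
        specs = tuned_specs([(0.0,) * 4], background=0.0)
        rec = synth.simulate_session(specs, 0, flat_trajectory(), 200, seed=4)
        timing, count = info.timing_and_count_information(
            rec, "t00", first_n=None, n_shuffles=10, seed=0
        )
        assert timing.corrected_info == 0.0
        assert count.corrected_info == 0.0


def _duplicate_neuron(rec):
    """Session with a byte-identical copy of neuron t00 as t00b."""
    dup = rec.spikes[rec.spikes["neuron_id"] == "t00"].assign(neuron_id="t00b")
    spikes = pd.concat([rec.spikes, dup], ignore_index=True)
    neurons = pd.concat(
        [rec.neurons, pd.DataFrame({"neuron_id": ["t00b"], "hemisphere": ["direct"]})],
        ignore_index=True,
    )
    return synth.SessionRecording(
        animal_id=rec.animal_id, day=rec.day, trials=rec.trials,
        spikes=spikes, neurons=neurons,
    )


class TestRedundancy:
    def test_single_neuron_hemisphere_p_is_exactly_zero(self):
        specs = tuned_specs([(80.0, 0.0, 0.0, 0.0)], background=2.0)
        rec = synth.simulate_session(specs, 0, flat_trajectory(), 120, seed=9)
        res = info.redundancy(rec, first_n=None, n_shuffles=10, seed=0)
        assert res.p_value_bits == 0.0
        assert res.redundancy == 0.0

    def test_duplicated_neurons_are_redundant(self):
        """Identical spike trains: ensemble adds nothing, the sum doubles."""
        specs = tuned_specs([(90.0, 0.0, 0.0, 0.0)], background=2.0)
        rec = synth.simulate_session(specs, 0, flat_trajectory(), 160, seed=17)
        res = info.redundancy(_duplicate_neuron(rec), first_n=None, n_shuffles=10, seed=0)
        assert res.redundancy > 0

    def test_disjointly_tuned_pair_less_redundant_than_duplicates(self):
        specs = tuned_specs(
            [(90.0, 90.0, 0.0, 0.0), (0.0, 0.0, 90.0, 90.0)], background=2.0
        )
        rec = synth.simulate_session(specs, 0, flat_trajectory(), 160, seed=23)
        disjoint = info.redundancy(rec, first_n=None, n_shuffles=10, seed=0)
        dup_specs = tuned_specs([(90.0, 90.0, 0.0, 0.0)], background=2.0)
        dup_rec = synth.simulate_session(dup_specs, 0, flat_trajectory(), 160, seed=23)
        duplicated = info.redundancy(
            _duplicate_neuron(dup_rec), first_n=None, n_shuffles=10, seed=0
        )
        assert disjoint.redundancy < duplicated.redundancy

    def test_empty_hemisphere_raises(self, untuned_session):
        with pytest.raises(decoder.DegenerateInputError):
            info.redundancy(untuned_session, hemisphere="indirect", first_n=None)


class TestInfoRedundancyCorrelation:
    def test_perfect_positive_and_negative(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert info.info_redundancy_correlation(x, x) == pytest.approx(1.0)
        assert info.info_redundancy_correlation(x, -x) == pytest.approx(-1.0)

    def test_five_point_series_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        assert info.info_redundancy_correlation(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        x = np.array([1.0, 2.0, 3.0])
        assert np.isnan(info.info_redundancy_correlation(x, np.ones(3)))

    def test_too_few_days_raises(self):
        with pytest.raises(ValueError):
            info.info_redundancy_correlation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
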