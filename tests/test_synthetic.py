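"""Generator contracts: planted states, Markov sequences, nuisance, cohort."""

import numpy as np
import pytest

from dynstates.io import load_truth, write_cohort
from dynstates.metrics import temporal_properties
from dynstates.synthetic import (
    CohortConfig,
    NuisanceConfig,
    default_transition_matrices,
    emit_subject_timecourses,
    generate_cohort,
    inject_nuisance,
    make_state_covariances,
    sample_state_sequence,
    stationary_distribution,
)


def pairwise_corr_distance(A, B):
    iu = np.triu_indices(A.shape[0], k=1)
    return 1 - np.corrcoef(A[iu], B[iu])[0, 1]


class TestStateCovariances:
    def test_single_state(self):
        (R,) = make_state_covariances(1, 5, 0.4, seed=3)
        assert R.shape == (5, 5)
        assert np.linalg.eigvalsh(R).min() > 0

    def test_determinism(self):
        a = make_state_covariances(4, 5, 0.4, seed=7)
        b = make_state_covariances(4, 5, 0.4, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_separation_constraint_direct_loop(self):
        states = make_state_covariances(4, 5, 0.4, seed=7)
        for i in range(4):
            assert np.linalg.eigvalsh(states[i]).min() > 0
            for j in range(i + 1, 4):
                assert pairwise_corr_distance(states[i], states[j]) >= 0.4

    def test_unattainable_separation_errors(self):
        with pytest.raises(ValueError):
            make_state_covariances(3, 5, 2.5, seed=0)
        with pytest.raises(RuntimeError):
            make_state_covariances(30, 5, 1.95, seed=0, max_attempts=200)


class TestStateSequence:
    def test_absorbing_chain(self):
        seq = sample_state_sequence(np.eye(4), [0, 1, 0, 0], T=50, seed=0)
        assert np.array_equal(seq, np.full(50, 2))

    def test_uniform_chain_occupancy(self):
        P = np.full((4, 4), 0.25)
        seq = sample_state_sequence(P, [0.25] * 4, T=100_000, seed=5)
        for s in range(1, 5):
            assert abs((seq == s).mean() - 0.25) < 0.01

    def test_geometric_dwell_law(self):
        # stay probability 0.9 -> mean dwell 1/(1-0.9) = 10
        P = np.full((4, 4), 0.1 / 3)
        np.fill_diagonal(P, 0.9)
        seq = sample_state_sequence(P, [0.25] * 4, T=100_000, seed=5)
        change = np.flatnonzero(seq[1:] != seq[:-1]) + 1
        runs = np.diff(np.concatenate(([0], change, [seq.size])))
        assert abs(runs.mean() - 10) / 10 < 0.05

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError):
            sample_state_sequence(np.ones((3, 3)), [1, 0, 0], T=10, seed=0)

    def test_stationary_distribution(self):
        P = default_transition_matrices()["patient"]
        pi = stationary_distribution(P)
        assert np.allclose(pi @ P, pi, atol=1e-12)


class TestEmission:
    def test_shape_and_determinism(self):
        covs = make_state_covariances(2, 5, 0.4, seed=1)
        seq = np.array([1, 2, 1, 1, 2] * 10)
        a = emit_subject_timecourses(seq, covs, seed=9)
        b = emit_subject_timecourses(seq, covs, seed=9)
        assert a.shape == (50, 5)
        assert np.array_equal(a, b)

    def test_law_of_large_numbers(self):
        covs = make_state_covariances(2, 5, 0.4, seed=1)
        seq = np.ones(50_000, dtype=int)
        X = emit_subject_timecourses(seq, covs, seed=2)
        S = np.cov(X.T)
        rel = np.linalg.norm(S - covs[0]) / np.linalg.norm(covs[0])
        assert rel < 0.05

    def test_state_out_of_range(self):
        covs = make_state_covariances(2, 5, 0.4, seed=1)
        with pytest.raises(ValueError):
            emit_subject_timecourses([1, 3], covs, seed=0)


class TestNuisance:
    def test_all_zero_config_is_identity(self, rng):
        X = rng.standard_normal((100, 5))
        cfg = NuisanceConfig(trend_amplitudes=(0, 0, 0), motion_gain=0, spike_rate=0)
        out, motion, spikes = inject_nuisance(X, cfg, seed=0)
        assert np.array_equal(out, X)
        assert motion.shape == (100, 6)
        assert spikes == []

    def test_spike_bookkeeping(self, rng):
        X = rng.standard_normal((500, 5))
        cfg = NuisanceConfig(trend_amplitudes=(0, 0, 0), motion_gain=0, spike_rate=0.02)
        out, _, spikes = inject_nuisance(X, cfg, seed=3)
        changed = np.argwhere(out != X)
        assert len(spikes) == len(changed)
        assert {(int(t), int(c)) for t, c in spikes} == {(int(t), int(c)) for t, c in changed}

    def test_cubic_trend_recovered_by_regression(self):
        X = np.zeros((400, 5))
        cfg = NuisanceConfig(trend_amplitudes=(0, 0, 1.0), motion_gain=0, spike_rate=0)
        out, _, _ = inject_nuisance(X, cfg, seed=4)
        t = np.linspace(-1, 1, 400)
        design = np.column_stack([np.ones(400), t, t**2, t**3])
        beta = np.linalg.lstsq(design, out, rcond=None)[0]
        fitted = design @ beta
        assert np.abs(out - fitted).max() < 1e-6

    def test_negative_spike_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            inject_nuisance(rng.standard_normal((50, 5)), NuisanceConfig(spike_rate=-1), 0)


class TestGenerateCohort:
    def test_file_contract(self, tmp_path):
        cfg = CohortConfig(n_patients=3, n_controls=3, n_timepoints=60, seed=11)
        subjects, truth = generate_cohort(cfg)
        manifest = write_cohort(subjects, truth, tmp_path)
        assert len(list(tmp_path.glob("*_timecourses.tsv"))) == 6
        import pandas as pd

        df = pd.read_csv(manifest)
        assert len(df) == 6
        assert (tmp_path / "truth.json").exists()
        loaded = load_truth(tmp_path / "truth.json")
        assert np.array_equal(loaded.n_transitions, truth.n_transitions)

    def test_truth_consistency_with_metrics_module(self):
        cfg = CohortConfig(n_patients=4, n_controls=4, seed=21)
        _, truth = generate_cohort(cfg)
        for i, seq in enumerate(truth.sequences):
            props = temporal_properties(seq, cfg.n_states)
            assert np.array_equal(props.fractional_windows, truth.fractional_windows[i])
            assert np.array_equal(props.mean_dwell_time, truth.mean_dwell_time[i])
            assert props.n_transitions == truth.n_transitions[i]

    def test_generator_is_pure_function_of_config(self):
        cfg = CohortConfig(n_patients=2, n_controls=2, n_timepoints=60, seed=5)
        s1, t1 = generate_cohort(cfg)
        s2, t2 = generate_cohort(cfg)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.data, b.data)
            assert a.sdmt == b.sdmt
        assert np.array_equal(t1.n_transitions, t2.n_transitions)

    def test_planted_group_effect_in_truth(self):
        # higher state-1 self-transition in patients -> higher true occupancy
        diffs = []
        for seed in range(10):
            cfg = CohortConfig(n_patients=50, n_controls=50, seed=seed)
            _, truth = generate_cohort(cfg)
            f1 = truth.fractional_windows[:, 0]
            diffs.append(f1[:50].mean() - f1[50:].mean())
        assert np.mean(diffs) > 0

    def test_score_model_correlation_sign(self):
        hits = 0
        for seed in range(10):
            cfg = CohortConfig(n_patients=40, n_controls=0, seed=seed)
            subjects, truth = generate_cohort(cfg)
            sdmt = np.array([s.sdmt for s in subjects])
            r = np.corrcoef(truth.n_transitions, sdmt)[0, 1]
            hits += r > 0
        assert hits >= 9

    def test_score_partial_correlation_recovery(self):
        # transitions -> SDMT link survives partialling out age/sex/education
        from dynstates.stats import partial_correlation

        hits = 0
        for seed in range(20):
            cfg = CohortConfig(n_patients=66, n_controls=0, seed=seed)
            subjects, truth = generate_cohort(cfg)
            covs = np.column_stack(
                [
                    [s.age for s in subjects],
                    [s.sex for s in subjects],
                    [s.education for s in subjects],
                ]
            )
            res = partial_correlation(
                truth.n_transitions, [s.sdmt for s in subjects], covs
            )
            hits += res.r > 0 and res.p < 0.05
        assert hits >= 16

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_states=1).validate()
        with pytest.raises(ValueError):
            CohortConfig(n_timepoints=35).validate()
        bad = default_transition_matrices()
        bad["patient"] = bad["patient"] * 0.5
        with pytest.raises(ValueError):
            CohortConfig(group_transition_matrices=bad).validate()
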