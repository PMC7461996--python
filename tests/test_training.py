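"""Templates, attractors, RLS updates and the three training steps."""

import dataclasses

import numpy as np
import pytest

from echodraw import (
    Instance,
    TemporalSignal,
    TrainingConfig,
    Trajectory2D,
    capture_attractors,
    compute_class_templates,
    init_weights,
    innate_train,
    readout_train,
    rls_p_update,
    separation_train,
    simulate,
    train_full,
)
from echodraw.benchmarks import standard_fixture
from echodraw.exceptions import DataError, ShapeError
from echodraw.training import _clipped_inverse


def _dataset_from_arrays(pairs, dt=1.0):
    counters = {}
    out = []
    for lab, arr in pairs:
        idx = counters.get(lab, 0)
        counters[lab] = idx + 1
        out.append(Instance(lab, TemporalSignal(arr, dt), idx))
    return out


class TestClassTemplates:
    def test_single_instance_template_is_that_instance(self, small_params, rng):
        arr = rng.random((small_params.n_in, small_params.sensory_steps))
        ds = _dataset_from_arrays([((0, 0), arr), ((1, 0), arr * 2)])
        tmpl = compute_class_templates(ds, small_params)
        assert np.array_equal(tmpl.templates[(0, 0)], arr)

    def test_opposite_instances_average_to_zero(self, small_params, rng):
        arr = rng.random((small_params.n_in, small_params.sensory_steps))
        ds = _dataset_from_arrays([((0, 0), arr), ((0, 0), -arr)])
        tmpl = compute_class_templates(ds, small_params)
        assert np.max(np.abs(tmpl.templates[(0, 0)])) < 1e-15

    def test_mean_matches_direct_oracle(self, small_params, rng):
        arrs = [rng.random((small_params.n_in, small_params.sensory_steps))
                for _ in range(3)]
        ds = _dataset_from_arrays([((0, 0), a) for a in arrs])
        tmpl = compute_class_templates(ds, small_params)
        assert np.max(
            np.abs(tmpl.templates[(0, 0)] - np.mean(arrs, axis=0))
        ) < 1e-12

    def test_missing_class_named_in_error(self, small_params, rng):
        arr = rng.random((small_params.n_in, small_params.sensory_steps))
        ds = _dataset_from_arrays([((0, 0), arr)])
        with pytest.raises(DataError, match="1, 1"):
            compute_class_templates(ds, small_params, classes=[(0, 0), (1, 1)])

    def test_variable_length_instances_are_rescaled(self, small_params, rng):
        short = rng.random((small_params.n_in, small_params.sensory_steps // 2))
        ds = _dataset_from_arrays([((0, 0), short), ((1, 0), short)])
        tmpl = compute_class_templates(ds, small_params)
        assert tmpl.templates[(0, 0)].shape == (
            small_params.n_in, small_params.sensory_steps
        )


class TestCaptureAttractors:
    def test_zero_template_zero_attractor(self, small_params, small_weights):
        tmpl = compute_class_templates(
            _dataset_from_arrays([
                ((0, 0), np.zeros((small_params.n_in,
                                   small_params.sensory_steps))),
            ]),
            small_params,
        )
        att = capture_attractors(tmpl, small_weights, small_params)
        assert not att[(0, 0)].values.any()

    def test_capture_is_deterministic_and_composes_with_simulate(
        self, small_params, small_weights, rng
    ):
        arr = 0.5 * rng.random((small_params.n_in, small_params.sensory_steps))
        tmpl = compute_class_templates(
            _dataset_from_arrays([((0, 0), arr)]), small_params
        )
        a = capture_attractors(tmpl, small_weights, small_params)
        b = capture_attractors(tmpl, small_weights, small_params)
        assert np.array_equal(a[(0, 0)].values, b[(0, 0)].values)
        direct = simulate(
            TemporalSignal(arr, small_params.dt), small_weights, small_params
        )
        assert np.array_equal(a[(0, 0)].values, direct.values)


class TestRlsPUpdate:
    def test_zero_vector_leaves_p_unchanged(self):
        P = np.eye(4) / 3.0
        assert np.array_equal(rls_p_update(P, np.zeros(4)), P)

    def test_symmetry_preserved(self):
        P = np.eye(5) / 100.0
        for k in range(50):
            v = np.eye(5)[k % 5]
            P = rls_p_update(P, v)
            assert np.max(np.abs(P - P.T)) < 1e-10

    def test_converges_to_regularized_inverse(self, rng):
        # Sherman-Morrison: after presenting each v_k once,
        # P = (alpha I + sum v v^T)^(-1) exactly
        alpha = 2.0
        V = rng.standard_normal((8, 5))
        P = np.eye(5) / alpha
        for v in V:
            P = rls_p_update(P, v)
        expected = np.linalg.inv(alpha * np.eye(5) + V.T @ V)
        assert np.max(np.abs(P - expected)) < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeError):
            rls_p_update(np.eye(3), np.zeros(4))


class TestClippedInverse:
    def test_plain_inverse_when_moderate(self):
        assert np.allclose(_clipped_inverse(np.array([0.5, -2.0]), 1e3),
                           [2.0, -0.5])

    def test_tiny_and_zero_components_clip(self):
        inv = _clipped_inverse(np.array([1e-15, -1e-15, 0.0]), 1e3)
        assert np.all(np.isfinite(inv))
        assert np.allclose(np.abs(inv), 1e3)
        assert inv[1] == -1e3


class TestSeparationTrain:
    def test_gamma_zero_is_exact_identity(self):
        train, _, _, params, config = standard_fixture(seed=0, hard=True)
        tmpl = compute_class_templates(train, params)
        w = init_weights(params, rng_seed=0, n_patterns=2)
        cfg = dataclasses.replace(config, gamma=0.0, epochs_separation=2)
        w2, hist = separation_train(w, tmpl, params, cfg)
        assert np.array_equal(w.W_in, w2.W_in)
        assert len(set(hist)) == 1

    def test_sp_increases_on_hard_fixture(self):
        train, _, _, params, config = standard_fixture(seed=0, hard=True)
        tmpl = compute_class_templates(train, params)
        w = init_weights(params, rng_seed=0, n_patterns=2)
        _, hist = separation_train(w, tmpl, params, config)
        assert hist[-1] > hist[0]

    def test_requires_two_classes(self, small_params, small_weights, rng):
        tmpl = compute_class_templates(
            _dataset_from_arrays([
                ((0, 0), rng.random((small_params.n_in,
                                     small_params.sensory_steps))),
            ]),
            small_params,
        )
        with pytest.raises(DataError):
            separation_train(small_weights, tmpl, small_params,
                             TrainingConfig())


class TestInnateTrain:
    def test_templates_are_a_fixed_point(self, small_params, small_weights, rng):
        # a dataset equal to the templates is already converged: no update
        arrs = {
            (0, 0): 0.4 * rng.random((small_params.n_in,
                                      small_params.sensory_steps)),
            (1, 0): 0.4 * rng.random((small_params.n_in,
                                      small_params.sensory_steps)),
        }
        ds = _dataset_from_arrays(list(arrs.items()))
        tmpl = compute_class_templates(ds, small_params)
        att = capture_attractors(tmpl, small_weights, small_params)
        cfg = TrainingConfig(epochs_innate=2)
        w2, hist = innate_train(small_weights, att, ds, small_params, cfg)
        assert np.array_equal(small_weights.W_res, w2.W_res)
        assert max(hist) < 1e-12

    def test_jittered_instances_converge_toward_attractor(self):
        train, _, _, params, config = standard_fixture(seed=0, hard=True)
        tmpl = compute_class_templates(train, params)
        w = init_weights(params, rng_seed=0, n_patterns=2)
        att = capture_attractors(tmpl, w, params)
        cfg = dataclasses.replace(config, epochs_innate=3)
        _, hist = innate_train(w, att, train, params, cfg)
        assert hist[-1] < hist[0]

    def test_update_cadence_changes_result_but_both_converge(self):
        train, _, _, params, config = standard_fixture(seed=0, hard=True)
        tmpl = compute_class_templates(train, params)
        w = init_weights(params, rng_seed=0, n_patterns=2)
        att = capture_attractors(tmpl, w, params)
        results = {}
        for ds_steps in (1, 2):
            cfg = dataclasses.replace(
                config, epochs_innate=3, delta_steps=ds_steps
            )
            w2, hist = innate_train(w, att, train, params, cfg)
            assert hist[-1] < hist[0]
            results[ds_steps] = w2.W_res
        assert not np.array_equal(results[1], results[2])

    def test_missing_attractor_rejected(self, small_params, small_weights, rng):
        arr = rng.random((small_params.n_in, small_params.sensory_steps))
        ds = _dataset_from_arrays([((0, 0), arr), ((1, 0), arr)])
        tmpl = compute_class_templates(
            _dataset_from_arrays([((0, 0), arr)]), small_params
        )
        att = capture_attractors(tmpl, small_weights, small_params)
        with pytest.raises(DataError):
            innate_train(small_weights, att, ds, small_params,
                         TrainingConfig())


class TestReadoutTrain:
    def _realizable_setup(self, small_params, small_weights, rng):
        arrs = {
            (0, 0): 0.5 * rng.random((small_params.n_in,
                                      small_params.sensory_steps)),
            (1, 1): 0.5 * rng.random((small_params.n_in,
                                      small_params.sensory_steps)),
        }
        ds = _dataset_from_arrays(list(arrs.items()))
        W0 = rng.standard_normal((small_params.n_res, 2)) * 0.3
        word_targets, attr_targets = {}, {}
        for lab, arr in arrs.items():
            rates = simulate(TemporalSignal(arr, small_params.dt),
                             small_weights, small_params)
            motor = rates.values[:, rates.phase_boundary:]
            word_targets[lab[0]] = Trajectory2D((W0.T @ motor).T)
            attr_targets[lab[1]] = Trajectory2D((W0.T @ motor).T)
        return ds, [word_targets, attr_targets], W0

    def test_recovers_planted_linear_readout(self, small_params,
                                             small_weights, rng):
        ds, targets, W0 = self._realizable_setup(small_params, small_weights,
                                                 rng)
        # weak ridge regularization so the exact planted map is reachable
        cfg = TrainingConfig(epochs_readout=20, alpha_readout=1.0)
        trained = readout_train(small_weights, ds, targets, small_params, cfg)
        # realizable targets: output MSE must be tiny
        for inst in ds:
            rates = simulate(inst.signal, small_weights, small_params)
            motor = rates.values[:, rates.phase_boundary:]
            out = (trained.W_out[0].T @ motor).T
            want = targets[0][inst.label[0]].xy
            assert np.mean((out - want) ** 2) < 1e-4

    def test_zero_targets_leave_readout_at_zero(self, small_params,
                                                small_weights, rng):
        ds, targets, _ = self._realizable_setup(small_params, small_weights,
                                                rng)
        zeros = {
            k: Trajectory2D(np.zeros((small_params.motor_steps, 2)))
            for k in (0, 1)
        }
        trained = readout_train(small_weights, ds, [zeros, zeros],
                                small_params, TrainingConfig(epochs_readout=2))
        for w in trained.W_out:
            assert not w.any()

    def test_swapping_target_sets_swaps_outputs(self, small_params,
                                                small_weights, rng):
        ds, targets, _ = self._realizable_setup(small_params, small_weights,
                                                rng)
        # make the two mappings genuinely different
        targets[1] = {k: Trajectory2D(t.xy * 0.5 + 0.1)
                      for k, t in targets[1].items()}
        cfg = TrainingConfig(epochs_readout=3)
        a = readout_train(small_weights, ds, targets, small_params, cfg)
        b = readout_train(small_weights, ds, [targets[1], targets[0]],
                          small_params, cfg)
        # labels are (0,0) and (1,1), so pattern-k target keys coincide and
        # swapping the mappings must exactly swap the trained blocks
        assert np.array_equal(a.W_out[0], b.W_out[1])
        assert np.array_equal(a.W_out[1], b.W_out[0])

    def test_wrong_target_length_rejected(self, small_params, small_weights,
                                          rng):
        ds, targets, _ = self._realizable_setup(small_params, small_weights,
                                                rng)
        bad = {k: Trajectory2D(t.xy[:-1]) for k, t in targets[0].items()}
        with pytest.raises(DataError):
            readout_train(small_weights, ds, [bad, targets[1]], small_params,
                          TrainingConfig())


class TestTrainFull:
    def test_deterministic_metrics_for_fixed_seed(self):
        train, _, targets, params, config = standard_fixture(seed=1, hard=False)
        cfg = dataclasses.replace(
            config, epochs_separation=2, epochs_innate=2, epochs_readout=2
        )
        a = train_full(train, targets, params, cfg)
        b = train_full(train, targets, params, cfg)
        assert a.sp_history == b.sp_history
        assert a.distance_history == b.distance_history
        assert a.errors == b.errors
        assert np.array_equal(a.weights.W_res, b.weights.W_res)

    def test_requires_two_classes(self, small_params, rng):
        arr = rng.random((small_params.n_in, small_params.sensory_steps))
        ds = _dataset_from_arrays([((0, 0), arr)])
        with pytest.raises(DataError):
            train_full(ds, [{}, {}], small_params, TrainingConfig())
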