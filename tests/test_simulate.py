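"""Developmental simulation: kernel correctness, phases and populations."""

import numpy as np
import pytest

from onoffrf import (
    ModelParams,
    ParameterError,
    SynapticWeights,
    apply_weight_constraints,
    excitatory_hebbian_step,
    inhibitory_step,
    initial_weights,
    load_population,
    run_population,
    run_pre_hearing,
    run_sound_phase,
    save_population,
)
from onoffrf.simulate import RULE_HEBBIAN, _run_phase, run_cell


def scalar_reference(x_on, x_off, w0, noise, p: ModelParams):
    """Hand-written per-step loop: voltage -> rate -> updates -> constraints."""
    won = w0.w_on_e.copy()
    woff = w0.w_off_e.copy()
    mon = -w0.w_on_i.copy()
    moff = -w0.w_off_i.copy()
    T, n = x_on.shape
    for t in range(T):
        u = 0.0
        for k in range(n):
            u += won[k] * x_on[t, k] + woff[k] * x_off[t, k]
            u -= mon[k] * x_on[t, k] + moff[k] * x_off[t, k]
        y = max(u - p.theta, 0.0)
        for k in range(n):
            won[k] += p.alpha_e * x_on[t, k] * y + noise[t, 0, k] * won[k]
            woff[k] += p.alpha_e * x_off[t, k] * y + noise[t, 1, k] * woff[k]
            mon[k] = max(mon[k] + p.alpha_i * x_on[t, k] * (y - p.rho), 0.0)
            moff[k] = max(moff[k] + p.alpha_i * x_off[t, k] * (y - p.rho), 0.0)
        won = np.clip(won, 0.0, 1.0)
        woff = np.clip(woff, 0.0, 1.0)
        won *= p.excit_l1 / won.sum()
        woff *= p.excit_l1 / woff.sum()
        if mon.sum() > 0:
            mon *= p.inhib_l1 / mon.sum()
        if moff.sum() > 0:
            moff *= p.inhib_l1 / moff.sum()
    return SynapticWeights(won, woff, -mon, -moff)


class TestKernelOracle:
    def test_twenty_step_toy_matches_scalar_reference(self, params):
        """Compiled kernel equals a hand-computed scalar loop to 1e-12."""
        rng = np.random.default_rng(99)
        T, n = 20, 10
        x_on = rng.uniform(0, 5, (T, n))
        x_off = rng.uniform(0, 5, (T, n))
        noise = rng.uniform(-params.eta_bound, params.eta_bound, (T, 2, n))
        w0 = SynapticWeights(np.full(n, 0.05), np.full(n, 0.05),
                             -rng.uniform(0, 0.1, n), -rng.uniform(0, 0.1, n))

        class FixedNoise:
            def uniform(self, lo, hi, size=None):
                return noise

        w_kernel, _, _ = _run_phase(x_on, x_off, w0.copy(), params, FixedNoise(),
                                    use_inhibition=True, rule=RULE_HEBBIAN)
        w_ref = scalar_reference(x_on, x_off, w0, noise, params)
        for name in ("w_on_e", "w_off_e", "w_on_i", "w_off_i"):
            assert np.allclose(getattr(w_kernel, name), getattr(w_ref, name),
                               atol=1e-12)

    def test_kernel_single_step_matches_public_rule_functions(self, params):
        """One kernel step equals composing the exposed rule operations."""
        rng = np.random.default_rng(5)
        x_on = rng.uniform(0, 5, (1, 10))
        x_off = rng.uniform(0, 5, (1, 10))
        noise = rng.uniform(-params.eta_bound, params.eta_bound, (1, 2, 10))
        w0 = SynapticWeights(np.full(10, 0.08), np.full(10, 0.12),
                             -rng.uniform(0, 0.2, 10), -rng.uniform(0, 0.2, 10))

        class FixedNoise:
            def uniform(self, lo, hi, size=None):
                return noise

        w_kernel, _, y = _run_phase(x_on, x_off, w0.copy(), params, FixedNoise(),
                                    use_inhibition=True, rule=RULE_HEBBIAN)

        class RowNoise:
            def uniform(self, lo, hi, size=None):
                return noise[0, RowNoise.row]

        from onoffrf import InputFrame, firing_rate, membrane_voltage
        u = membrane_voltage(w0, InputFrame.from_drives(x_on[0], x_off[0]))
        rate = float(firing_rate(u, params.theta))
        assert rate == pytest.approx(y[0], abs=1e-12)
        RowNoise.row = 0
        won = excitatory_hebbian_step(w0.w_on_e, x_on[0], rate, params, RowNoise())
        RowNoise.row = 1
        woff = excitatory_hebbian_step(w0.w_off_e, x_off[0], rate, params, RowNoise())
        mon = inhibitory_step(-w0.w_on_i, x_on[0], rate, params)
        moff = inhibitory_step(-w0.w_off_i, x_off[0], rate, params)
        expected = apply_weight_constraints(
            SynapticWeights(won, woff, -mon, -moff), params)
        for name in ("w_on_e", "w_off_e", "w_on_i", "w_off_i"):
            assert np.allclose(getattr(w_kernel, name), getattr(expected, name),
                               atol=1e-12)


class TestPreHearing:
    def test_on_off_symmetry_without_noise(self, short_params):
        p = short_params.replace(eta_bound=0.0)
        w = run_pre_hearing(p, seed=4)
        assert np.array_equal(w.w_on_e, w.w_off_e)
        assert np.array_equal(w.w_on_i, w.w_off_i)

    def test_deterministic(self, short_params):
        a = run_pre_hearing(short_params, seed=8)
        b = run_pre_hearing(short_params, seed=8)
        for name in ("w_on_e", "w_off_e", "w_on_i", "w_off_i"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_weights_valid_and_normalised(self, short_params):
        w = run_pre_hearing(short_params, seed=4)
        w.validate(short_params, check_sums=True, atol=1e-9)


class TestSoundPhase:
    def test_unknown_condition(self, short_params):
        w = initial_weights(short_params)
        with pytest.raises(ParameterError):
            run_sound_phase(w, short_params, "mystery", seed=0)

    def test_excitation_only_keeps_inhibition_silent(self, short_params):
        start = run_pre_hearing(short_params, seed=4)
        rec = run_sound_phase(start, short_params, "excitation_only", seed=1)
        for w in rec.snapshots.values():
            assert np.all(w.w_on_i == 0) and np.all(w.w_off_i == 0)

    def test_scaling_only_preserves_weight_ratios(self, short_params):
        start = run_pre_hearing(short_params, seed=4)
        rec = run_sound_phase(start, short_params, "scaling_only", seed=1)
        w_end = rec.snapshots[max(rec.snapshots)]
        r0 = start.w_on_e / start.w_off_e
        r1 = w_end.w_on_e / w_end.w_off_e
        assert np.allclose(r0, r1, rtol=1e-9)

    def test_snapshots_satisfy_invariants(self, short_params):
        start = run_pre_hearing(short_params, seed=4)
        rec = run_sound_phase(start, short_params, "single_channel", seed=2)
        assert set(rec.snapshots) >= {0, short_params.t_young, short_params.t_adult}
        for w in rec.snapshots.values():
            w.validate(short_params, check_sums=True, atol=1e-9)

    def test_snapshot_zero_is_hearing_onset(self, short_params):
        start = run_pre_hearing(short_params, seed=4)
        rec = run_sound_phase(start, short_params, "single_channel", seed=2)
        assert np.array_equal(rec.snapshots[0].w_on_e, start.w_on_e)


class TestPopulation:
    def test_single_cell_equals_direct_run(self, short_params):
        pop = run_population(1, short_params, "single_channel", master_seed=42)
        ss = np.random.SeedSequence(42)
        direct = run_cell(short_params, "single_channel", ss.spawn(1)[0])
        a = pop[0].snapshots[short_params.t_adult]
        b = direct.snapshots[short_params.t_adult]
        assert np.array_equal(a.w_on_e, b.w_on_e)

    def test_population_reproducible(self, short_params):
        a = run_population(3, short_params, "single_channel", master_seed=7)
        b = run_population(3, short_params, "single_channel", master_seed=7)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.snapshots[0].w_on_e, rb.snapshots[0].w_on_e)
            t = max(ra.snapshots)
            assert np.array_equal(ra.snapshots[t].w_on_e, rb.snapshots[t].w_on_e)

    def test_invalid_count(self, short_params):
        with pytest.raises(ParameterError):
            run_population(0, short_params, "single_channel", master_seed=0)

    def test_hdf5_roundtrip(self, short_params, tmp_path):
        pop = run_population(2, short_params, "single_channel", master_seed=9)
        path = tmp_path / "pop.h5"
        save_population(pop, path)
        back = load_population(path, short_params)
        assert len(back) == 2
        for ra, rb in zip(pop, back):
            assert ra.condition == rb.condition
            for t in ra.snapshots:
                assert np.array_equal(ra.snapshots[t].w_on_e,
                                      rb.snapshots[t].w_on_e)
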