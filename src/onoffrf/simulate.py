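"""Two-phase developmental simulation of single cells and populations.

Each model cell is simulated through (1) a pre-hearing phase driven by
spontaneous activity shared between ON and OFF inputs, which develops
matched ON/OFF tuning, and (2) a sound-exposure phase driven by stochastic
ON/OFF switching sequences, during which ON and OFF receptive fields
diverge.  Weights are snapshotted at configurable times (at least Hearing
Onset t=0, Young t=1500 and Adult t=100000 of the sound phase).

The per-step update loop (voltage -> rate -> Hebbian/inhibitory update ->
clip + L1 normalisation) is JIT-compiled with numba; the pure-Python rule
functions in :mod:`onoffrf.plasticity` define the reference semantics and
the test suite pins the compiled kernel to them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from numba import njit

from .network import SynapticWeights, apply_tuning, initial_weights, tuning_matrix_for
from .params import ModelParams, ParameterError
from .stimuli import (
    StimulusTraces,
    events_to_traces,
    generate_independent_sequences,
    generate_spontaneous_traces,
    generate_switching_sequence,
    traces_from_event_pair,
)

__all__ = [
    "SimulationRecord",
    "CONDITIONS",
    "run_pre_hearing",
    "run_sound_phase",
    "run_population",
    "save_population",
    "load_population",
]

CONDITIONS = (
    "single_channel",
    "overlapping",
    "independent_on_off",
    "excitation_only",
    "scaling_only",
)

RULE_HEBBIAN = 0
RULE_SCALING = 1

log = logging.getLogger(__name__)


# --------------------------------------------------------------------- #
# compiled inner loop
# --------------------------------------------------------------------- #

@njit(cache=True)
def _phase_kernel(x_on, x_off, w, noise,
                  theta, alpha_e, alpha_i, rho,
                  excit_l1, inhib_l1,
                  exc_joint, inh_joint, inhib_literal,
                  w_lo, w_hi,
                  use_inhibition, inhib_plastic, rule, scaling_factor,
                  snap_times, snaps, y_out):
    """Run one plasticity phase in place.

    ``w`` is (4, N): excitatory ON, excitatory OFF, inhibitory ON
    *magnitude*, inhibitory OFF *magnitude*.  ``noise`` is (T, 2, N)
    per-step multiplicative synaptic noise for the two excitatory classes.
    ``snap_times`` are step counts after which to record ``w`` into
    ``snaps`` (a time of 0 is handled by the caller).  Returns 0 on
    success, 1 if an excitatory class collapses to zero sum.
    """
    T = x_on.shape[0]
    N = x_on.shape[1]
    mean_y = 0.0
    n_obs = 0
    snap_ptr = 0
    n_snaps = snap_times.shape[0]
    while snap_ptr < n_snaps and snap_times[snap_ptr] == 0:
        snaps[snap_ptr] = w
        snap_ptr += 1

    for t in range(T):
        # voltage and rate
        u = 0.0
        for k in range(N):
            u += w[0, k] * x_on[t, k] + w[1, k] * x_off[t, k]
        if use_inhibition:
            for k in range(N):
                u -= w[2, k] * x_on[t, k] + w[3, k] * x_off[t, k]
        y = u - theta
        if y < 0.0:
            y = 0.0
        y_out[t] = y

        # excitatory update
        if rule == 0:
            for k in range(N):
                w[0, k] += alpha_e * x_on[t, k] * y + noise[t, 0, k] * w[0, k]
                w[1, k] += alpha_e * x_off[t, k] * y + noise[t, 1, k] * w[1, k]
        else:
            if y > mean_y:
                f = 1.0 - scaling_factor
            elif y < mean_y:
                f = 1.0 + scaling_factor
            else:
                f = 1.0
            for k in range(N):
                w[0, k] *= f
                w[1, k] *= f
            n_obs += 1
            mean_y += (y - mean_y) / n_obs

        # inhibitory update (on magnitudes)
        if use_inhibition and inhib_plastic:
            sgn = -1.0 if inhib_literal else 1.0
            for k in range(N):
                m = w[2, k] + sgn * alpha_i * x_on[t, k] * (y - rho)
                w[2, k] = m if m > 0.0 else 0.0
                m = w[3, k] + sgn * alpha_i * x_off[t, k] * (y - rho)
                w[3, k] = m if m > 0.0 else 0.0

        # constraints: clip + L1 normalisation
        s_on = 0.0
        s_off = 0.0
        for k in range(N):
            if w[0, k] < w_lo:
                w[0, k] = w_lo
            elif w[0, k] > w_hi:
                w[0, k] = w_hi
            if w[1, k] < w_lo:
                w[1, k] = w_lo
            elif w[1, k] > w_hi:
                w[1, k] = w_hi
            s_on += w[0, k]
            s_off += w[1, k]
        if exc_joint:
            if s_on + s_off <= 0.0:
                return 1
            f = 2.0 * excit_l1 / (s_on + s_off)
            for k in range(N):
                w[0, k] *= f
                w[1, k] *= f
        else:
            if s_on <= 0.0 or s_off <= 0.0:
                return 1
            f_on = excit_l1 / s_on
            f_off = excit_l1 / s_off
            for k in range(N):
                w[0, k] *= f_on
                w[1, k] *= f_off

        if use_inhibition and inhib_plastic:
            si_on = 0.0
            si_off = 0.0
            for k in range(N):
                si_on += w[2, k]
                si_off += w[3, k]
            if inh_joint:
                if si_on + si_off > 0.0:
                    f = inhib_l1 / (si_on + si_off)
                    for k in range(N):
                        w[2, k] *= f
                        w[3, k] *= f
            else:
                if si_on > 0.0:
                    f = inhib_l1 / si_on
                    for k in range(N):
                        w[2, k] *= f
                if si_off > 0.0:
                    f = inhib_l1 / si_off
                    for k in range(N):
                        w[3, k] *= f

        while snap_ptr < n_snaps and snap_times[snap_ptr] == t + 1:
            snaps[snap_ptr] = w
            snap_ptr += 1

    return 0


# --------------------------------------------------------------------- #
# phase drivers
# --------------------------------------------------------------------- #

def _w_to_kernel(w: SynapticWeights) -> np.ndarray:
    """(4, N) kernel layout with inhibitory magnitudes."""
    a = w.as_array().copy()
    a[2] = -a[2]
    a[3] = -a[3]
    return np.ascontiguousarray(a)

def _w_from_kernel(a: np.ndarray) -> SynapticWeights:
    b = a.copy()
    b[2] = -b[2]
    b[3] = -b[3]
    return SynapticWeights.from_array(b)


def _draw_noise(rng: np.random.Generator, n_steps: int, n: int,
                eta_bound: float) -> np.ndarray:
    if eta_bound > 0:
        return rng.uniform(-eta_bound, eta_bound, size=(n_steps, 2, n))
    return np.zeros((n_steps, 2, n))


def _run_phase(x_on, x_off, w0: SynapticWeights, params: ModelParams,
               rng_noise: np.random.Generator, *, use_inhibition: bool,
               rule: int, inhib_plastic: bool = True, snapshot_times=()):
    """Shared driver around the compiled kernel."""
    T = x_on.shape[0]
    n = params.n_channels
    snap_times = np.array(sorted(set(int(t) for t in snapshot_times)), dtype=np.int64)
    if snap_times.size and (snap_times[0] < 0 or snap_times[-1] > T):
        raise ParameterError("snapshot times must lie within the phase duration")
    snaps = np.zeros((snap_times.size, 4, n))
    y_out = np.zeros(T)
    if rule == RULE_HEBBIAN:
        noise = _draw_noise(rng_noise, T, n, params.eta_bound)
    else:
        noise = np.zeros((T, 2, n))
    w = _w_to_kernel(w0)
    lo, hi = params.w_bounds
    status = _phase_kernel(
        np.ascontiguousarray(x_on), np.ascontiguousarray(x_off), w, noise,
        params.theta, params.alpha_e, params.alpha_i, params.rho,
        params.excit_l1, params.inhib_l1,
        params.excit_l1_mode == "joint",
        params.inhib_l1_mode == "joint",
        params.inhib_rule == "literal",
        lo, hi,
        use_inhibition, inhib_plastic, rule, params.scaling_factor,
        snap_times, snaps, y_out,
    )
    if status != 0:
        raise RuntimeError("an excitatory weight class collapsed to zero during "
                           "the run; the L1 constraint cannot be satisfied")
    snapshots = {int(t): _w_from_kernel(s) for t, s in zip(snap_times, snaps)}
    return _w_from_kernel(w), snapshots, y_out


def run_pre_hearing(params: ModelParams, seed, *,
                    inhibition: bool = True) -> SynapticWeights:
    """Simulate the pre-hearing phase and return the hearing-onset weights.

    Starting from uniform excitatory weights 1/(2N) and zero inhibitory
    weights, the cell is driven for ``n_steps_pre`` steps by spontaneous
    activity (identical for ON and OFF inputs, independent across
    channels, tuning-weighted) with full plasticity.  Because ON and OFF
    inputs see the same drive, the ON and OFF weight vectors at hearing
    onset match up to synaptic noise.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_spont, ss_noise = ss.spawn(2)
    spont = generate_spontaneous_traces(params, np.random.default_rng(ss_spont))
    tuning = tuning_matrix_for(params)
    x = apply_tuning(tuning, spont.on_drive)
    w_final, _, _ = _run_phase(
        x, x, initial_weights(params), params,
        np.random.default_rng(ss_noise),
        use_inhibition=inhibition, rule=RULE_HEBBIAN,
    )
    return w_final


@dataclass
class SimulationRecord:
    """Outcome of one cell's developmental run.

    ``snapshots`` maps sound-phase times (0 = hearing onset) to weight
    records; ``rate_summary`` holds the mean output rate and the fraction
    of suprathreshold steps during the sound phase.
    """

    condition: str
    seed: int
    snapshots: dict
    params: ModelParams
    rate_summary: dict = field(default_factory=dict)

    @property
    def adult(self) -> SynapticWeights:
        return self.snapshots[max(self.snapshots)]


def _sound_traces(params: ModelParams, condition: str, rng_seed) -> StimulusTraces:
    if condition == "overlapping":
        params = params.overlapping()
        train = generate_switching_sequence(params, "overlapping", rng_seed)
        return events_to_traces(train, params, params.input_max)
    if condition == "independent_on_off":
        train_on, train_off = generate_independent_sequences(params, rng_seed)
        return traces_from_event_pair(train_on, train_off, params, params.input_max)
    # single_channel stimulus for the remaining conditions
    train = generate_switching_sequence(params, "single_channel", rng_seed)
    return events_to_traces(train, params, params.input_max)


def run_sound_phase(start: SynapticWeights, params: ModelParams,
                    condition: str, seed) -> SimulationRecord:
    """Simulate the sound-exposure phase from the hearing-onset weights.

    ``condition`` selects the stimulus and rule set: ``single_channel``
    (default model), ``overlapping`` (independent channels, p_off = 1/500),
    ``independent_on_off`` (ON pulses from one sequence, OFF pulses from
    another), ``excitation_only`` (inhibitory inputs and rule removed) and
    ``scaling_only`` (excitatory Hebbian rule replaced by homeostatic
    synaptic scaling).  Snapshots are recorded at ``params.snapshot_times``
    plus t_young and t_adult (clipped to the phase duration).
    """
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_stim, ss_noise = ss.spawn(2)
    traces = _sound_traces(params, condition, ss_stim)
    T = params.n_steps_sound
    if traces.n_steps < T:
        raise RuntimeError("stimulus shorter than the sound phase")
    snap_times = sorted({0, params.t_young, params.t_adult, *params.snapshot_times})
    snap_times = [t for t in snap_times if 0 <= t <= T]
    use_inh = condition != "excitation_only"
    # the scaling control replaces the whole activity-dependent rule set:
    # excitatory Hebbian -> homeostatic scaling, inhibitory weights frozen
    # (inhibitory inputs still contribute to the voltage)
    rule = RULE_SCALING if condition == "scaling_only" else RULE_HEBBIAN
    inhib_plastic = condition != "scaling_only"
    w0 = start.copy()
    if not use_inh:
        w0.w_on_i = np.zeros_like(w0.w_on_i)
        w0.w_off_i = np.zeros_like(w0.w_off_i)
    _, snapshots, y = _run_phase(
        traces.on_drive[:T], traces.off_drive[:T], w0, params,
        np.random.default_rng(ss_noise),
        use_inhibition=use_inh, rule=rule, inhib_plastic=inhib_plastic,
        snapshot_times=snap_times,
    )
    seed_int = int(ss.entropy) if isinstance(ss.entropy, int) and ss.entropy < 2**63 else -1
    return SimulationRecord(
        condition=condition,
        seed=seed_int,
        snapshots=snapshots,
        params=params,
        rate_summary={"mean_rate": float(y.mean()),
                      "active_fraction": float(np.mean(y > 0))},
    )


def run_cell(params: ModelParams, condition: str, seed) -> SimulationRecord:
    """Full development of one cell: pre-hearing then sound exposure."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_pre, ss_sound = ss.spawn(2)
    # the excitation_only condition removes *evoked* inhibition: the
    # pre-hearing (spontaneous) phase always runs with full plasticity
    w_onset = run_pre_hearing(params, ss_pre, inhibition=True)
    return run_sound_phase(w_onset, params, condition, ss_sound)


def run_population(n_cells: int, params: ModelParams, condition: str,
                   master_seed, progress: bool = False) -> list:
    """Independent end-to-end runs of ``n_cells`` cells.

    Per-cell seed streams are spawned from ``master_seed``, so results are
    reproducible and independent of execution order.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    ss = master_seed if isinstance(master_seed, np.random.SeedSequence) \
        else np.random.SeedSequence(master_seed)
    children = ss.spawn(n_cells)
    records = []
    for k, cell_ss in enumerate(children):
        rec = run_cell(params, condition, cell_ss)
        rec.seed = k
        records.append(rec)
        if progress:
            log.info("%s: cell %d/%d done", condition, k + 1, n_cells)
    return records


# --------------------------------------------------------------------- #
# persistence
# --------------------------------------------------------------------- #

def save_population(records: list, path) -> None:
    """Persist a population of simulation records to HDF5."""
    with h5py.File(path, "w") as fh:
        for k, rec in enumerate(records):
            g = fh.create_group(f"cell_{k}")
            g.attrs["condition"] = rec.condition
            g.attrs["seed"] = rec.seed
            for t, w in rec.snapshots.items():
                gs = g.create_group(f"snapshot_{t}")
                for name in ("w_on_e", "w_off_e", "w_on_i", "w_off_i"):
                    gs.create_dataset(name, data=getattr(w, name))
            for key, val in rec.rate_summary.items():
                g.attrs[key] = val


def load_population(path, params: ModelParams) -> list:
    """Load a population saved by :func:`save_population`."""
    records = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys(), key=lambda s: int(s.split("_")[1])):
            g = fh[key]
            snapshots = {}
            for sk in g.keys():
                t = int(sk.split("_")[1])
                gs = g[sk]
                snapshots[t] = SynapticWeights(
                    gs["w_on_e"][...], gs["w_off_e"][...],
                    gs["w_on_i"][...], gs["w_off_i"][...],
                )
            records.append(SimulationRecord(
                condition=str(g.attrs["condition"]),
                seed=int(g.attrs["seed"]),
                snapshots=snapshots,
                params=params,
                rate_summary={k: float(v) for k, v in g.attrs.items()
                              if k not in ("condition", "seed")},
            ))
    return records
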