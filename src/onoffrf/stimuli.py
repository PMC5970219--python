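"""Stimulus generation: spontaneous activity, ON/OFF sound sequences, probes.

The model is driven entirely by internally generated stimuli:

* pre-hearing spontaneous activity — rectified, filtered uniform noise,
  one independent trace per frequency channel, shared by ON and OFF inputs
  (and by excitation and inhibition);
* sound-evoked sequences — two-state Markov chains that switch a frequency
  channel ON and OFF; each onset pulses the ON inputs by 1, each offset
  pulses the OFF inputs by 1, and pulses decay exponentially with time
  constant ``tau_decay``;
* probe stimuli — sustained tones for frequency response areas and
  stepwise frequency-modulated sweeps.

Event times are kept in :class:`EventTrain`; realised drive arrays
(time x channel, after Gaussian tuning where applicable) in
:class:`StimulusTraces`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import lfilter

from .network import apply_tuning, tuning_matrix_for
from .params import ModelParams, ParameterError

__all__ = [
    "EventTrain",
    "StimulusTraces",
    "generate_spontaneous_traces",
    "generate_switching_sequence",
    "generate_independent_sequences",
    "events_to_traces",
    "traces_from_event_pair",
    "fm_sweep_events",
    "tone_probe_traces",
]

log = logging.getLogger(__name__)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# --------------------------------------------------------------------- #
# containers
# --------------------------------------------------------------------- #

@dataclass
class EventTrain:
    """Per-channel sorted onset/offset times of a switching sound sequence.

    Within each channel, onsets and offsets strictly alternate starting
    with an onset; a trailing un-closed onset (sound still ON at the end)
    is allowed.
    """

    onsets: list
    offsets: list
    n_steps: int

    def __post_init__(self):
        self.onsets = [np.asarray(a, dtype=np.int64) for a in self.onsets]
        self.offsets = [np.asarray(a, dtype=np.int64) for a in self.offsets]
        if len(self.onsets) != len(self.offsets):
            raise ValueError("onsets and offsets must cover the same channels")

    @property
    def n_channels(self) -> int:
        return len(self.onsets)

    @property
    def n_events(self) -> int:
        return int(sum(len(a) for a in self.onsets) + sum(len(a) for a in self.offsets))

    def validate(self) -> None:
        for c, (on, off) in enumerate(zip(self.onsets, self.offsets)):
            if len(on) - len(off) not in (0, 1):
                raise ValueError(f"channel {c}: onset/offset counts differ by >1")
            merged = np.empty(len(on) + len(off), dtype=np.int64)
            merged[0::2] = on
            merged[1::2] = off
            if merged.size and (np.any(np.diff(merged) <= 0)
                                or merged[0] < 0 or merged[-1] >= self.n_steps):
                raise ValueError(f"channel {c}: events not strictly alternating in range")

    def shifted(self, dt: int) -> "EventTrain":
        """Time-shift all events by ``dt`` steps (duration grows to fit)."""
        return EventTrain(
            [a + dt for a in self.onsets],
            [a + dt for a in self.offsets],
            self.n_steps + dt,
        )


@dataclass
class StimulusTraces:
    """Realised drive arrays delivered to the ON and OFF input populations.

    ``kind`` records provenance: ``spontaneous`` traces are stimulus-level
    (per-channel mean 1, tuning applied downstream), while ``sound``,
    ``sweep`` and ``probe`` traces are already tuning-weighted inputs.
    """

    on_drive: np.ndarray
    off_drive: np.ndarray
    kind: str
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.on_drive = np.asarray(self.on_drive, dtype=float)
        self.off_drive = np.asarray(self.off_drive, dtype=float)
        if self.on_drive.shape != self.off_drive.shape:
            raise ValueError("ON and OFF drive arrays must share a shape")

    @property
    def n_steps(self) -> int:
        return self.on_drive.shape[0]

    def to_hdf5(self, path, group: str = "/") -> None:
        with h5py.File(path, "a") as fh:
            g = fh.require_group(group)
            for name in ("on_drive", "off_drive"):
                if name in g:
                    del g[name]
                g.create_dataset(name, data=getattr(self, name), compression="gzip")
            g.attrs["kind"] = self.kind
            if self.seed is not None:
                g.attrs["seed"] = self.seed

    @classmethod
    def from_hdf5(cls, path, group: str = "/") -> "StimulusTraces":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            return cls(
                on_drive=g["on_drive"][...],
                off_drive=g["off_drive"][...],
                kind=str(g.attrs["kind"]),
                seed=int(g.attrs["seed"]) if "seed" in g.attrs else None,
            )


# --------------------------------------------------------------------- #
# spontaneous (pre-hearing) activity
# --------------------------------------------------------------------- #

def generate_spontaneous_traces(params: ModelParams, seed,
                                n_steps: int | None = None,
                                _max_retries: int = 5) -> StimulusTraces:
    """Pre-hearing spontaneous stimulus: filtered, rectified uniform noise.

    Per channel: uniform noise in (-0.5, 0.5) is filtered by a first-order
    exponential filter with time constant ``spont_tc``, the constant
    ``theta_x`` is subtracted, negative values are set to zero, and the
    sequence is rescaled to a temporal mean of 1.  ON and OFF drives are
    identical (spontaneous activity is shared between ON and OFF inputs),
    and channels are mutually independent.
    """
    T = int(n_steps if n_steps is not None else params.n_steps_pre)
    if T <= 0:
        raise ParameterError("n_steps must be positive")
    n = params.n_channels
    rng = _rng(seed)
    a = float(np.exp(-1.0 / params.spont_tc))
    for attempt in range(_max_retries):
        raw = rng.uniform(-0.5, 0.5, size=(T, n))
        # x(t) = a x(t-1) + (1-a) raw(t)
        x = lfilter([1.0 - a], [1.0, -a], raw, axis=0)
        x = np.maximum(x - params.theta_x, 0.0)
        means = x.mean(axis=0)
        if np.all(means > 0):
            x /= means
            return StimulusTraces(x, x.copy(), kind="spontaneous",
                                  seed=seed if isinstance(seed, int) else None)
        log.warning(
            "spontaneous trace had an all-zero channel after rectification; "
            "regenerating with a perturbed stream (attempt %d)", attempt + 1,
        )
    raise RuntimeError(
        "could not generate spontaneous activity with positive mean in every "
        f"channel after {_max_retries} attempts (theta_x={params.theta_x} too high?)"
    )


# --------------------------------------------------------------------- #
# sound-evoked switching sequences
# --------------------------------------------------------------------- #

def _alternating_switch_times(rng, p_switch_on: float, p_switch_off: float,
                              n_steps: int) -> np.ndarray:
    """Event times of a two-state chain starting OFF at step 0.

    At each step the chain leaves OFF with probability ``p_switch_on`` and
    leaves ON with probability ``p_switch_off``; dwell times are therefore
    geometric.  Returns the strictly increasing switch times (< n_steps),
    alternating onset, offset, onset, ...
    """
    expected = max(16, int(2.5 * n_steps * min(p_switch_on, p_switch_off)) + 16)
    times: list[np.ndarray] = []
    t = 0
    while t < n_steps:
        d_off = rng.geometric(p_switch_on, size=expected)
        d_on = rng.geometric(p_switch_off, size=expected)
        dwell = np.empty(2 * expected, dtype=np.int64)
        dwell[0::2] = d_off
        dwell[1::2] = d_on
        ts = t + np.cumsum(dwell)
        times.append(ts)
        t = int(ts[-1])
    all_times = np.concatenate(times)
    return all_times[all_times < n_steps]


def generate_switching_sequence(params: ModelParams, mode: str, seed,
                                n_steps: int | None = None) -> EventTrain:
    """Stochastic ON/OFF sound sequence.

    ``single_channel``: a global chain — when silent, a uniformly random
    channel switches ON with probability ``p_off`` per step; the ON channel
    switches OFF with probability ``p_on`` per step; at most one channel is
    ON at any time.  ``overlapping``: every channel runs an independent
    chain with the same probabilities, so multiple frequencies can play
    simultaneously.
    """
    T = int(n_steps if n_steps is not None else params.n_steps_sound)
    n = params.n_channels
    rng = _rng(seed)
    onsets: list[list[int]] = [[] for _ in range(n)]
    offsets: list[list[int]] = [[] for _ in range(n)]

    if mode == "single_channel":
        times = _alternating_switch_times(rng, params.p_off, params.p_on, T)
        ons = times[0::2]
        offs = times[1::2]
        chans = rng.integers(0, n, size=len(ons))
        for k, (c, t_on) in enumerate(zip(chans, ons)):
            onsets[int(c)].append(int(t_on))
            if k < len(offs):
                offsets[int(c)].append(int(offs[k]))
    elif mode == "overlapping":
        for c in range(n):
            times = _alternating_switch_times(rng, params.p_off, params.p_on, T)
            onsets[c] = times[0::2].tolist()
            offsets[c] = times[1::2].tolist()
    else:
        raise ParameterError(f"unknown switching mode {mode!r}")

    train = EventTrain([np.array(a, dtype=np.int64) for a in onsets],
                       [np.array(a, dtype=np.int64) for a in offsets], T)
    train.validate()
    return train


def generate_independent_sequences(params: ModelParams, seed,
                                   n_steps: int | None = None,
                                   mode: str = "single_channel"):
    """Two statistically independent switching sequences.

    Used for the independent-ON/OFF condition: ON inputs are pulsed by the
    onsets of the first train, OFF inputs by the offsets of the second, so
    that onsets and offsets no longer alternate within a channel.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s1, s2 = ss.spawn(2)
    train_on = generate_switching_sequence(params, mode, np.random.default_rng(s1), n_steps)
    train_off = generate_switching_sequence(params, mode, np.random.default_rng(s2), n_steps)
    return train_on, train_off


# --------------------------------------------------------------------- #
# events -> input traces
# --------------------------------------------------------------------- #

def _impulse_array(times_per_channel, n_steps: int, n_channels: int) -> np.ndarray:
    imp = np.zeros((n_steps, n_channels))
    for c, ts in enumerate(times_per_channel):
        if len(ts):
            np.add.at(imp[:, c], np.asarray(ts, dtype=np.int64), 1.0)
    return imp


def _decay_filter(imp: np.ndarray, tau: float) -> np.ndarray:
    # pulse of 1 at the event step, multiplied by exp(-1/tau) each later step
    decay = float(np.exp(-1.0 / tau))
    return lfilter([1.0], [1.0, -decay], imp, axis=0)


def traces_from_event_pair(on_train: EventTrain, off_train: EventTrain,
                           params: ModelParams, rescale_max: float,
                           kind: str = "sound") -> StimulusTraces:
    """Input traces whose ON pulses come from ``on_train`` onsets and OFF
    pulses from ``off_train`` offsets (the two may be the same train).

    Pulses decay exponentially (time constant ``tau_decay``), are passed
    through the Gaussian tuning matrix, and the two arrays are jointly
    rescaled so their global maximum equals ``rescale_max``.
    """
    if on_train.n_steps != off_train.n_steps:
        raise ValueError("event trains must share a duration")
    T_steps, n = on_train.n_steps, params.n_channels
    on_imp = _impulse_array(on_train.onsets, T_steps, n)
    off_imp = _impulse_array(off_train.offsets, T_steps, n)
    tuning = tuning_matrix_for(params)
    on = apply_tuning(tuning, _decay_filter(on_imp, params.tau_decay))
    off = apply_tuning(tuning, _decay_filter(off_imp, params.tau_decay))
    peak = max(on.max(initial=0.0), off.max(initial=0.0))
    if peak > 0:
        scale = rescale_max / peak
        on *= scale
        off *= scale
    else:
        warnings.warn("empty event train: traces are all zero, no rescaling applied")
    return StimulusTraces(on, off, kind=kind, meta={"rescale_max": rescale_max})


def events_to_traces(events: EventTrain, params: ModelParams,
                     rescale_max: float, kind: str = "sound") -> StimulusTraces:
    """Input traces of a single train: onsets drive ON, offsets drive OFF."""
    return traces_from_event_pair(events, events, params, rescale_max, kind=kind)


# --------------------------------------------------------------------- #
# probes
# --------------------------------------------------------------------- #

def fm_sweep_events(direction: str, params: ModelParams,
                    start_channel: int = 0,
                    offset_timing: str = "band_exit") -> EventTrain:
    """Stepwise FM sweep: a tone presented in one frequency band at a time,
    advancing one band every ``sweep_interval`` steps (UP: ascending,
    DOWN: descending, circular boundary), for ``sweep_steps`` steps.

    Each presentation contributes one onset event; its offset event falls,
    under the default ``band_exit`` timing, at the moment the sweep moves
    on to the next band — so a band's offset coincides with its
    neighbour's onset, the coincidence that lets ON and OFF drive summate
    when a sweep leaves the OFF-preferred band while entering the
    ON-preferred one.  ``offset_timing="next_step"`` instead places the
    offset one step after the onset (an isolated one-step tone per band).
    """
    if direction not in ("UP", "DOWN"):
        raise ParameterError("direction must be 'UP' or 'DOWN'")
    if offset_timing not in ("band_exit", "next_step"):
        raise ParameterError("offset_timing must be 'band_exit' or 'next_step'")
    n = params.n_channels
    step = 1 if direction == "UP" else -1
    dt_off = params.sweep_interval if offset_timing == "band_exit" else 1
    times = np.arange(0, params.sweep_steps, params.sweep_interval)
    onsets: list[list[int]] = [[] for _ in range(n)]
    offsets: list[list[int]] = [[] for _ in range(n)]
    for k, t in enumerate(times):
        c = (start_channel + step * k) % n
        onsets[c].append(int(t))
        offsets[c].append(int(t) + dt_off)
    train = EventTrain([np.array(a) for a in onsets],
                       [np.array(a) for a in offsets],
                       int(times[-1]) + dt_off + 1)
    train.validate()
    return train


def tone_probe_traces(channel: int, intensity: float,
                      params: ModelParams) -> StimulusTraces:
    """Drive of a sustained probe tone used to measure FRAs.

    One onset pulse of size ``intensity`` in ``channel`` at t = 0 drives the
    ON inputs; one offset pulse of the same size at t = ``probe_duration``
    drives the OFF inputs.  Both are tuning-weighted but *not* globally
    rescaled: the pulse size carries the sound level.
    """
    if intensity <= 0:
        raise ParameterError("probe intensity must be positive")
    n = params.n_channels
    if not 0 <= channel < n:
        raise ParameterError(f"channel must be in [0, {n})")
    T_steps = int(params.probe_duration + params.response_window)
    on_imp = np.zeros((T_steps, n))
    off_imp = np.zeros((T_steps, n))
    on_imp[0, channel] = intensity
    off_imp[params.probe_duration, channel] = intensity
    tuning = tuning_matrix_for(params)
    on = apply_tuning(tuning, _decay_filter(on_imp, params.tau_decay))
    off = apply_tuning(tuning, _decay_filter(off_imp, params.tau_decay))
    return StimulusTraces(on, off, kind="probe",
                          meta={"channel": channel, "intensity": intensity})
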