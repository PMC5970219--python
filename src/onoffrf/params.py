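"""Model parameters for the ON/OFF receptive-field development model.

All constants of the rate-based feedforward model live in a single frozen,
validated record so that every stage of the pipeline (stimulus generation,
plasticity, probing, analysis) reads from one source of truth.  Units are
the model's own: one time step is interpreted as 1 ms when durations are
quoted in milliseconds, rates and inputs are dimensionless ("arbitrary
units"), and frequency-channel indices map to octaves via
``octaves_per_index`` (10 channels span 5 octaves, so an index difference
of 2 equals 1 octave).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = ["ModelParams", "ParameterError"]


class ParameterError(ValueError):
    """Raised when a model parameter violates its documented constraints."""


_TUNING_DENOMS = ("2sigma", "2sigma2")
_L1_MODES = ("per_class", "joint")
_INHIB_RULES = ("magnitude", "literal")


@dataclass(frozen=True)
class ModelParams:
    """All constants of the threshold-linear neuron model and its probes.

    Attributes
    ----------
    n_channels:
        Number of frequency channels N; the neuron receives 4N inputs
        (excitatory/inhibitory x ON/OFF).
    theta:
        Firing threshold of the threshold-linear transfer y = max(u - theta, 0).
    sigma:
        Width (in channel indices) of the Gaussian input tuning.
    alpha_e, alpha_i:
        Excitatory (Hebbian) and inhibitory learning rates.
    rho:
        Target output rate of the inhibitory rule.
    eta_bound:
        Half-width of the uniform multiplicative synaptic noise applied to
        excitatory weights each step.
    tau_decay:
        Decay time constant (steps) of onset/offset-evoked input pulses.
    p_on:
        Per-step probability that a sound that is ON switches OFF.
    p_off:
        Per-step probability that a silent channel switches ON
        (1/50 single-channel condition, 1/500 overlapping condition).
    input_max, sweep_input_max:
        Global maxima to which evoked input traces are rescaled during
        sound exposure and FM-sweep probing respectively.  Both default
        to 40: sweep inputs are generated exactly like sound-evoked
        inputs, and a probe much weaker than the threshold-to-weight
        scale (u <= ceiling x total net weight, with theta = 2.5) could
        never drive the neuron at all.
    spont_tc:
        Time constant (steps) of the exponential filter applied to the
        uniform noise that generates pre-hearing spontaneous activity.
    theta_x:
        Constant subtracted from the filtered spontaneous noise before
        rectification.
    excit_l1 / inhib_l1:
        Targets of the L1 weight normalisation (see ``excit_l1_mode`` /
        ``inhib_l1_mode`` for whether the target applies per ON/OFF class
        or jointly to both).
    octaves_per_index:
        Conversion from channel-index differences to octaves (0.5: ten
        channels span five octaves).
    t_young, t_adult:
        Sound-exposure time points labelled "Young" and "Adult".
    scaling_factor:
        Step size of the homeostatic synaptic-scaling alternative rule.
    """

    n_channels: int = 10
    theta: float = 2.5
    sigma: float = 1.5
    alpha_e: float = 1e-4
    alpha_i: float = 1e-5
    rho: float = 0.01
    eta_bound: float = 0.0025
    tau_decay: float = 10.0
    p_on: float = 1.0 / 50.0
    p_off: float = 1.0 / 50.0
    n_steps_pre: int = 100_000
    n_steps_sound: int = 100_000
    input_max: float = 40.0
    sweep_input_max: float = 40.0
    spont_tc: float = 5.0
    theta_x: float = 0.1
    excit_l1: float = 1.0
    inhib_l1: float = 1.0
    w_bounds: tuple[float, float] = (0.0, 1.0)
    octaves_per_index: float = 0.5
    t_young: int = 1500
    t_adult: int = 100_000
    scaling_factor: float = 1e-5

    # -- conventions exposed as switches (ambiguities in the written model) --
    tuning_denominator: str = "2sigma"       # exp(-d^2/(2 sigma)) as printed
    excit_l1_mode: str = "per_class"         # ON^e and OFF^e each sum to excit_l1
    inhib_l1_mode: str = "per_class"         # ON^i and OFF^i each sum to -inhib_l1
    inhib_rule: str = "magnitude"            # Vogels update applied to magnitudes

    # -- probing protocol --
    probe_intensities: tuple[float, ...] = tuple(float(v) for v in np.linspace(19.5, 65.0, 8))
    probe_duration: int = 100                # steps the probe tone stays ON
    response_window: int = 30                # steps averaged after on/offset pulse
    sweep_steps: int = 3000
    sweep_interval: int = 50                 # steps between sweep presentations

    # -- bookkeeping --
    snapshot_times: tuple[int, ...] = (0, 500, 1000, 1500, 5000, 20000, 100_000)

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ParameterError("n_channels must be >= 2")
        for name in ("p_on", "p_off"):
            p = getattr(self, name)
            if not 0.0 < p <= 1.0:
                raise ParameterError(f"{name} must lie in (0, 1], got {p}")
        if self.sigma <= 0:
            raise ParameterError("sigma must be positive")
        if self.tau_decay < 1:
            raise ParameterError("tau_decay must be >= 1 step")
        if self.theta < 0:
            raise ParameterError("theta must be non-negative")
        for name in ("n_steps_pre", "n_steps_sound", "probe_duration",
                     "response_window", "sweep_steps", "sweep_interval",
                     "t_young", "t_adult"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ParameterError(f"{name} must be a positive integer, got {v!r}")
        if self.spont_tc <= 0:
            raise ParameterError("spont_tc must be positive")
        if self.eta_bound < 0:
            raise ParameterError("eta_bound must be non-negative")
        if self.excit_l1 <= 0 or self.inhib_l1 < 0:
            raise ParameterError("L1 targets must be positive (excit) / non-negative (inhib)")
        lo, hi = self.w_bounds
        if not lo < hi:
            raise ParameterError("w_bounds must be an increasing pair")
        if self.tuning_denominator not in _TUNING_DENOMS:
            raise ParameterError(f"tuning_denominator must be one of {_TUNING_DENOMS}")
        if self.excit_l1_mode not in _L1_MODES or self.inhib_l1_mode not in _L1_MODES:
            raise ParameterError(f"L1 modes must be one of {_L1_MODES}")
        if self.inhib_rule not in _INHIB_RULES:
            raise ParameterError(f"inhib_rule must be one of {_INHIB_RULES}")
        if any(i <= 0 for i in self.probe_intensities):
            raise ParameterError("probe intensities must be positive")
        if self.input_max <= 0 or self.sweep_input_max <= 0:
            raise ParameterError("rescale ceilings must be positive")

    # ------------------------------------------------------------------ #

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def overlapping(self) -> "ModelParams":
        """Parameters for the overlapping-sound condition (p_off = 1/500)."""
        return self.replace(p_off=1.0 / 500.0)

    @property
    def decay_factor(self) -> float:
        """Per-step multiplicative decay of evoked input pulses."""
        return float(np.exp(-1.0 / self.tau_decay))

    @property
    def initial_excitatory_weight(self) -> float:
        """Uniform initial value of every excitatory weight, 1/(2N)."""
        return 1.0 / (2 * self.n_channels)

    # -- serialisation ------------------------------------------------- #

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["probe_intensities"] = [float(v) for v in self.probe_intensities]
        d["snapshot_times"] = [int(v) for v in self.snapshot_times]
        d["w_bounds"] = [float(v) for v in self.w_bounds]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("probe_intensities", "snapshot_times", "w_bounds"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
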