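"""Learning rules: excitatory Hebbian, inhibitory rate rule, synaptic scaling.

Three rules act on the synaptic weights:

* excitatory Hebbian with multiplicative synaptic noise,
  ``dw_i = alpha_e * x_i * y + eta_i * w_i`` with
  ``eta_i ~ U(-eta_bound, eta_bound)`` drawn per synapse per step;
* a rate-based inhibitory rule (Vogels-type),
  ``dw_i = alpha_i * x_i * (y - rho)``, applied by default to the weight
  *magnitudes* so inhibition strengthens onto active inputs when the
  output exceeds its target rate ``rho`` (co-tuning); the literal signed
  form is available via ``params.inhib_rule = "literal"``;
* a homeostatic synaptic-scaling alternative that multiplies all
  excitatory weights by ``1 -/+ scaling_factor`` whenever the output is
  above/below its running mean since simulation start.

Because Hebbian growth is unstable, a constraint step bounds excitatory
weights to [0, 1] and rescales weights to fixed L1 targets after every
update.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import SynapticWeights
from .params import ModelParams

__all__ = [
    "ScalingState",
    "excitatory_hebbian_step",
    "inhibitory_step",
    "apply_weight_constraints",
    "synaptic_scaling_step",
]


@dataclass
class ScalingState:
    """Running mean of the output rate, used by the synaptic-scaling rule."""

    running_mean_y: float = 0.0
    n_obs: int = 0

    def update(self, y: float) -> None:
        self.n_obs += 1
        self.running_mean_y += (y - self.running_mean_y) / self.n_obs


def excitatory_hebbian_step(w_e: np.ndarray, x_e: np.ndarray, y: float,
                            params: ModelParams, rng: np.random.Generator,
                            ) -> np.ndarray:
    """One Hebbian update of one excitatory weight class (pre-constraint).

    ``w'_i = w_i + alpha_e x_i y + eta_i w_i`` with ``eta_i`` uniform in
    ``(-eta_bound, eta_bound)``, independent per synapse and per step.
    The noise is multiplicative, so silent synapses (w = 0) do not drift.
    """
    w_e = np.asarray(w_e, dtype=float)
    eta = rng.uniform(-params.eta_bound, params.eta_bound, size=w_e.shape)
    return w_e + params.alpha_e * np.asarray(x_e, dtype=float) * y + eta * w_e


def inhibitory_step(m_i: np.ndarray, x_i: np.ndarray, y: float,
                    params: ModelParams) -> np.ndarray:
    """One update of one inhibitory weight class, in magnitude form.

    ``m'_j = max(m_j + alpha_i x_j (y - rho), 0)``; the stored signed
    weight is ``w = -m``.  With the default magnitude convention
    inhibition grows onto active inputs whenever the output rate exceeds
    ``rho``, producing excitatory/inhibitory co-tuning.  The "literal"
    convention applies the printed update to the signed weights instead
    (equivalent to negating the drive term).
    """
    m_i = np.asarray(m_i, dtype=float)
    drive = params.alpha_i * np.asarray(x_i, dtype=float) * (y - params.rho)
    if params.inhib_rule == "magnitude":
        m = m_i + drive
    else:  # literal: dw = alpha x (y - rho) on w = -m  =>  dm = -drive
        m = m_i - drive
    return np.maximum(m, 0.0)


def _rescale_to(vecs: list[np.ndarray], target: float) -> None:
    """In-place multiplicative rescale of the concatenated vectors to sum
    ``target``; skipped when everything is zero."""
    total = float(sum(v.sum() for v in vecs))
    if total > 0.0:
        f = target / total
        for v in vecs:
            v *= f


def apply_weight_constraints(w: SynapticWeights, params: ModelParams,
                             ) -> SynapticWeights:
    """Clip and L1-normalise all four weight classes (returns a new record).

    Excitatory weights are clipped to ``w_bounds`` then multiplicatively
    rescaled to the L1 target — per class (ON and OFF each summing to
    ``excit_l1``) or jointly (both together summing to ``2 * excit_l1``),
    per ``params.excit_l1_mode``.  Inhibitory magnitudes are rescaled to
    ``inhib_l1`` the same way (``inhib_l1_mode``), except that an all-zero
    class (the initial condition) is left untouched.
    """
    lo, hi = params.w_bounds
    on_e = np.clip(np.asarray(w.w_on_e, dtype=float), lo, hi)
    off_e = np.clip(np.asarray(w.w_off_e, dtype=float), lo, hi)
    if params.excit_l1_mode == "per_class":
        for v in (on_e, off_e):
            if v.sum() <= 0.0:
                raise ValueError(
                    "an excitatory weight class collapsed to zero; the L1 "
                    "constraint cannot be satisfied"
                )
        _rescale_to([on_e], params.excit_l1)
        _rescale_to([off_e], params.excit_l1)
    else:
        if on_e.sum() + off_e.sum() <= 0.0:
            raise ValueError(
                "all excitatory weights collapsed to zero; the L1 constraint "
                "cannot be satisfied"
            )
        _rescale_to([on_e, off_e], 2.0 * params.excit_l1)

    m_on = np.maximum(-np.asarray(w.w_on_i, dtype=float), 0.0)
    m_off = np.maximum(-np.asarray(w.w_off_i, dtype=float), 0.0)
    if params.inhib_l1_mode == "per_class":
        _rescale_to([m_on], params.inhib_l1)
        _rescale_to([m_off], params.inhib_l1)
    else:
        _rescale_to([m_on, m_off], params.inhib_l1)

    return SynapticWeights(on_e, off_e, -m_on, -m_off)


def synaptic_scaling_step(w_e_classes, y: float, state: ScalingState,
                          params: ModelParams):
    """Homeostatic scaling of all excitatory weights (alternative rule).

    If ``y`` exceeds the running mean output since simulation start, every
    excitatory weight is multiplied by ``1 - scaling_factor``; if it falls
    below, by ``1 + scaling_factor``; at exact equality nothing changes.
    The running mean is then updated with ``y``.  Ratios between weights
    are preserved exactly (the update is uniform and multiplicative).
    """
    if y > state.running_mean_y:
        f = 1.0 - params.scaling_factor
    elif y < state.running_mean_y:
        f = 1.0 + params.scaling_factor
    else:
        f = 1.0
    scaled = [np.asarray(v, dtype=float) * f for v in w_e_classes]
    state.update(y)
    return scaled, state
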