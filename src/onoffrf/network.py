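"""Threshold-linear neuron, Gaussian input tuning and synaptic weight state.

The model neuron receives 4N inputs: N excitatory ON, N excitatory OFF,
N inhibitory ON and N inhibitory OFF.  Its voltage is the weighted sum of
all inputs and the output rate is the rectified voltage, y = max(u - theta, 0).
Inputs share a Gaussian tuning over frequency channels with a circular
boundary (channel 0 and channel N-1 are neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams, ParameterError

__all__ = [
    "TuningMatrix",
    "SynapticWeights",
    "InputFrame",
    "build_tuning_matrix",
    "apply_tuning",
    "membrane_voltage",
    "firing_rate",
    "initial_weights",
    "circular_distance",
]


def circular_distance(i, j, n: int):
    """Shortest index distance on a ring of ``n`` channels."""
    d = np.abs(np.asarray(i) - np.asarray(j))
    return np.minimum(d, n - d)


def build_tuning_matrix(sigma: float, n: int, denominator: str = "2sigma") -> np.ndarray:
    """Gaussian tuning matrix ``T[i, j] = exp(-d(i,j)^2 / denom)``.

    ``d`` is the circular index distance, so channel 0 and channel n-1 are
    neighbours.  ``denominator`` selects ``2*sigma`` (the model's printed
    convention) or the textbook ``2*sigma**2``; both yield a symmetric
    circulant matrix with unit diagonal.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be positive")
    if n < 2:
        raise ParameterError("need at least 2 channels")
    idx = np.arange(n)
    d = circular_distance(idx[:, None], idx[None, :], n)
    if denominator == "2sigma":
        denom = 2.0 * sigma
    elif denominator == "2sigma2":
        denom = 2.0 * sigma**2
    else:
        raise ParameterError(f"unknown tuning denominator {denominator!r}")
    return np.exp(-(d.astype(float) ** 2) / denom)


def tuning_matrix_for(params: ModelParams) -> np.ndarray:
    """Tuning matrix implied by a parameter record."""
    return build_tuning_matrix(params.sigma, params.n_channels, params.tuning_denominator)


def apply_tuning(T: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Input vector (or time x channel array) produced by stimulus ``s``.

    Each input is a tuning-weighted sum of the stimulus channels,
    x_i = sum_j T[i, j] s_j.  ``s`` may be a length-N vector or an
    (n_steps, N) array; the result has the same shape.
    """
    T = np.asarray(T, dtype=float)
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != T.shape[1]:
        raise ValueError(
            f"stimulus has {s.shape[-1]} channels but tuning matrix is {T.shape}"
        )
    # T is symmetric, so right-multiplication matches T @ s per time step.
    return s @ T.T


@dataclass
class SynapticWeights:
    """The four length-N weight vectors of one model neuron.

    Excitatory weights live in [0, 1]; inhibitory weights are stored as the
    (non-positive) signed efficacies.  ``validate`` checks bounds and, when
    requested, the L1 normalisation targets.
    """

    w_on_e: np.ndarray
    w_off_e: np.ndarray
    w_on_i: np.ndarray
    w_off_i: np.ndarray

    def __post_init__(self):
        self.w_on_e = np.asarray(self.w_on_e, dtype=float)
        self.w_off_e = np.asarray(self.w_off_e, dtype=float)
        self.w_on_i = np.asarray(self.w_on_i, dtype=float)
        self.w_off_i = np.asarray(self.w_off_i, dtype=float)
        n = self.w_on_e.shape[0]
        for name in ("w_off_e", "w_on_i", "w_off_i"):
            if getattr(self, name).shape != (n,):
                raise ValueError("all four weight vectors must share one length")

    @property
    def n(self) -> int:
        return self.w_on_e.shape[0]

    def copy(self) -> "SynapticWeights":
        return SynapticWeights(
            self.w_on_e.copy(), self.w_off_e.copy(),
            self.w_on_i.copy(), self.w_off_i.copy(),
        )

    def as_array(self) -> np.ndarray:
        """(4, N) stack in the order on_e, off_e, on_i, off_i."""
        return np.stack([self.w_on_e, self.w_off_e, self.w_on_i, self.w_off_i])

    @classmethod
    def from_array(cls, a: np.ndarray) -> "SynapticWeights":
        a = np.asarray(a, dtype=float)
        if a.shape[0] != 4:
            raise ValueError("expected a (4, N) array")
        return cls(a[0].copy(), a[1].copy(), a[2].copy(), a[3].copy())

    def validate(self, params: ModelParams | None = None, check_sums: bool = False,
                 atol: float = 1e-9) -> None:
        """Raise if bounds (and optionally L1 targets) are violated."""
        lo, hi = (0.0, 1.0) if params is None else params.w_bounds
        for name in ("w_on_e", "w_off_e"):
            w = getattr(self, name)
            if w.min() < lo - atol or w.max() > hi + atol:
                raise ValueError(f"{name} outside [{lo}, {hi}]")
        for name in ("w_on_i", "w_off_i"):
            if getattr(self, name).max() > atol:
                raise ValueError(f"{name} must be non-positive")
        if check_sums and params is not None:
            if params.excit_l1_mode == "per_class":
                for name in ("w_on_e", "w_off_e"):
                    if abs(getattr(self, name).sum() - params.excit_l1) > atol:
                        raise ValueError(f"{name} sum off its L1 target")
            else:
                if abs(self.w_on_e.sum() + self.w_off_e.sum()
                       - 2 * params.excit_l1) > atol:
                    raise ValueError("joint excitatory sum off its L1 target")


@dataclass
class InputFrame:
    """The 4N input values at a single time step.

    Excitatory and inhibitory inputs are identical by construction
    (x_on_e = x_on_i, x_off_e = x_off_i); the class keeps all four for
    symmetry with the weight record.
    """

    x_on_e: np.ndarray
    x_off_e: np.ndarray
    x_on_i: np.ndarray
    x_off_i: np.ndarray

    @classmethod
    def from_drives(cls, x_on: np.ndarray, x_off: np.ndarray) -> "InputFrame":
        x_on = np.asarray(x_on, dtype=float)
        x_off = np.asarray(x_off, dtype=float)
        return cls(x_on, x_off, x_on, x_off)


def membrane_voltage(w: SynapticWeights, x: InputFrame) -> float:
    """Voltage u = sum over all 4N synapses of weight times input."""
    for wa, xa in ((w.w_on_e, x.x_on_e), (w.w_off_e, x.x_off_e),
                   (w.w_on_i, x.x_on_i), (w.w_off_i, x.x_off_i)):
        if np.shape(wa) != np.shape(xa):
            raise ValueError("weight/input length mismatch")
    return float(
        w.w_on_e @ x.x_on_e + w.w_off_e @ x.x_off_e
        + w.w_on_i @ x.x_on_i + w.w_off_i @ x.x_off_i
    )


def firing_rate(u, theta: float):
    """Threshold-linear transfer: y = u - theta if u > theta, else 0."""
    return np.maximum(np.asarray(u, dtype=float) - theta, 0.0)


def initial_weights(params: ModelParams) -> SynapticWeights:
    """Initial state: excitatory weights uniform at 1/(2N), inhibitory zero."""
    n = params.n_channels
    w0 = np.full(n, params.initial_excitatory_weight)
    z = np.zeros(n)
    return SynapticWeights(w0.copy(), w0.copy(), z.copy(), z.copy())
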