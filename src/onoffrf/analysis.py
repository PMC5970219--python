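"""Probing trained model cells and population statistics.

A trained cell is probed with plasticity frozen:

* **FRAs** — sustained tones at every (channel, intensity) pair; the ON
  response is the mean rate in a fixed window after the onset pulse, the
  OFF response the mean rate after the offset pulse.
* **CFs** — the response-weighted centre of mass of each FRA surface.
  Channels live on a ring, so the default centre of mass is circular
  (vector mean); index differences convert to octaves at 0.5 oct/index.
* **FM sweeps** — stepwise ascending and descending sweeps; the
  selectivity index is (rate_up - rate_down) / (rate_up + rate_down).

Population helpers compute the divergence statistics (mean |CF_diff|,
two-sample Kolmogorov-Smirnov tests between time points) and the
correlation between signed CF difference and sweep selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .network import SynapticWeights, firing_rate
from .params import ModelParams, ParameterError
from .stimuli import events_to_traces, fm_sweep_events, tone_probe_traces

__all__ = [
    "ModelFRA",
    "SweepResult",
    "UndefinedCFError",
    "measure_model_fra",
    "center_of_mass_cf",
    "cf_difference_octaves",
    "measure_sweep_selectivity",
    "population_table",
    "population_divergence_stats",
    "cfdiff_selectivity_correlation",
]


class UndefinedCFError(ValueError):
    """Raised when a CF is requested from an all-zero response surface."""


@dataclass
class ModelFRA:
    """ON and OFF response surfaces (channels x intensities) of one cell."""

    on_resp: np.ndarray
    off_resp: np.ndarray
    intensity_axis: np.ndarray

    def __post_init__(self):
        self.on_resp = np.asarray(self.on_resp, dtype=float)
        self.off_resp = np.asarray(self.off_resp, dtype=float)
        self.intensity_axis = np.asarray(self.intensity_axis, dtype=float)
        if self.on_resp.shape != self.off_resp.shape:
            raise ValueError("ON and OFF surfaces must share a shape")
        if self.on_resp.shape[1] != self.intensity_axis.shape[0]:
            raise ValueError("intensity axis does not match the surfaces")


@dataclass
class SweepResult:
    """Mean rates to UP and DOWN sweeps and the selectivity index."""

    rate_up: float
    rate_down: float
    selectivity: float
    undefined: bool = False


def _net_weights(w: SynapticWeights):
    """Signed per-channel net ON and OFF weights (excitation + inhibition)."""
    return w.w_on_e + w.w_on_i, w.w_off_e + w.w_off_i


def measure_model_fra(w: SynapticWeights, params: ModelParams) -> ModelFRA:
    """Measure ON and OFF FRAs of a frozen cell.

    For each channel a probe tone is presented at each intensity of
    ``params.probe_intensities``; responses are mean rates in a
    ``response_window``-step window starting at the onset pulse (ON) and
    at the offset pulse (OFF).  Because the cell is linear above
    threshold, the probe drive is computed once per channel at unit
    intensity and scaled.
    """
    n = params.n_channels
    intensities = np.asarray(params.probe_intensities, dtype=float)
    w_on_net, w_off_net = _net_weights(w)
    win = params.response_window
    dur = params.probe_duration
    on_resp = np.zeros((n, intensities.size))
    off_resp = np.zeros((n, intensities.size))
    for c in range(n):
        probe = tone_probe_traces(c, 1.0, params)
        u_unit = probe.on_drive @ w_on_net + probe.off_drive @ w_off_net
        # rates scale non-linearly with intensity through the threshold
        y = firing_rate(intensities[None, :] * u_unit[:, None], params.theta)
        on_resp[c] = y[:win].mean(axis=0)
        off_resp[c] = y[dur:dur + win].mean(axis=0)
    return ModelFRA(on_resp, off_resp, intensities)


def center_of_mass_cf(resp: np.ndarray, circular: bool = True) -> float:
    """Response-weighted mean channel index of an FRA surface.

    With ``circular=True`` (default) the centre of mass is computed as a
    weighted circular mean over the channel ring, which is well defined
    for cells tuned across the wrap-around; the result lies in [0, N).
    With ``circular=False`` the plain weighted mean index is returned.
    """
    resp = np.asarray(resp, dtype=float)
    weights = resp.sum(axis=tuple(range(1, resp.ndim))) if resp.ndim > 1 else resp
    total = weights.sum()
    if total <= 0:
        raise UndefinedCFError("all-zero response surface has no centre of mass")
    n = weights.shape[0]
    idx = np.arange(n)
    if not circular:
        return float((weights * idx).sum() / total)
    ang = 2.0 * np.pi * idx / n
    mean_ang = np.arctan2((weights * np.sin(ang)).sum(),
                          (weights * np.cos(ang)).sum())
    return float((mean_ang * n / (2.0 * np.pi)) % n)


def cf_difference_octaves(on_cf: float, off_cf: float,
                          params: ModelParams) -> float:
    """Signed ON-minus-OFF CF difference in octaves, wrapped to the
    shorter circular arc (a tie at exactly half the ring resolves
    positive)."""
    n = params.n_channels
    d = (on_cf - off_cf + n / 2.0) % n - n / 2.0
    if d == -n / 2.0:
        d = n / 2.0
    return float(d * params.octaves_per_index)


def fra_cf_pair(fra: ModelFRA, circular: bool = True):
    """(ON CF, OFF CF) centre-of-mass indices of an FRA pair."""
    return (center_of_mass_cf(fra.on_resp, circular),
            center_of_mass_cf(fra.off_resp, circular))


def measure_sweep_selectivity(w: SynapticWeights, params: ModelParams,
                              start_channel: int = 0) -> SweepResult:
    """Mean rates to UP and DOWN FM sweeps and the selectivity index.

    Sweeps are built by :func:`fm_sweep_events` (one-step tones advancing
    one channel per ``sweep_interval`` steps, inputs rescaled so their
    maximum is ``sweep_input_max``) and played to the frozen cell; mean
    rates are taken over the full ``sweep_steps`` window.  When neither
    direction evokes any output the selectivity is reported as 0 with the
    ``undefined`` flag set.
    """
    w_on_net, w_off_net = _net_weights(w)
    rates = {}
    for direction in ("UP", "DOWN"):
        ev = fm_sweep_events(direction, params, start_channel=start_channel)
        tr = events_to_traces(ev, params, params.sweep_input_max, kind="sweep")
        u = tr.on_drive @ w_on_net + tr.off_drive @ w_off_net
        y = firing_rate(u, params.theta)
        rates[direction] = float(y[:params.sweep_steps].mean())
    up, down = rates["UP"], rates["DOWN"]
    if up + down <= 0:
        return SweepResult(up, down, 0.0, undefined=True)
    return SweepResult(up, down, (up - down) / (up + down))


# --------------------------------------------------------------------- #
# population statistics
# --------------------------------------------------------------------- #

def population_table(records, params: ModelParams | None = None,
                     times=None, sweeps: bool = False,
                     circular: bool = True) -> pd.DataFrame:
    """Per-cell, per-snapshot CF table (and optionally sweep responses).

    Columns: cell, time, on_cf, off_cf, cf_diff_oct (NaN when a surface is
    all zero); with ``sweeps=True`` (adult snapshot only): rate_up,
    rate_down, selectivity.
    """
    rows = []
    for k, rec in enumerate(records):
        p = params or rec.params
        snap_times = sorted(rec.snapshots) if times is None else times
        t_last = max(rec.snapshots)
        for t in snap_times:
            w = rec.snapshots[t]
            fra = measure_model_fra(w, p)
            row = {"cell": k, "time": t, "condition": rec.condition}
            try:
                on_cf, off_cf = fra_cf_pair(fra, circular)
                row.update(on_cf=on_cf, off_cf=off_cf,
                           cf_diff_oct=cf_difference_octaves(on_cf, off_cf, p))
            except UndefinedCFError:
                row.update(on_cf=np.nan, off_cf=np.nan, cf_diff_oct=np.nan)
            if sweeps and t == t_last:
                sw = measure_sweep_selectivity(w, p)
                row.update(rate_up=sw.rate_up, rate_down=sw.rate_down,
                           selectivity=sw.selectivity,
                           selectivity_defined=not sw.undefined)
            rows.append(row)
    return pd.DataFrame(rows)


def population_divergence_stats(records, t_a: int, t_b: int,
                                params: ModelParams | None = None,
                                table: pd.DataFrame | None = None) -> dict:
    """Mean |CF_diff| at two time points plus a two-sample KS test.

    Cells with an undefined CF at either time are excluded (their count is
    reported).  Requires at least two cells with defined CFs at both
    times.
    """
    if table is None:
        table = population_table(records, params, times=[t_a, t_b])
    piv = table.pivot(index="cell", columns="time", values="cf_diff_oct")
    ok = piv[[t_a, t_b]].notna().all(axis=1)
    a = piv.loc[ok, t_a].abs().to_numpy()
    b = piv.loc[ok, t_b].abs().to_numpy()
    if len(a) < 2:
        raise ValueError("need >= 2 cells with defined CFs at both times")
    ks = stats.ks_2samp(a, b)
    return {
        "t_a": t_a, "t_b": t_b,
        "mean_abs_cf_diff_a": float(a.mean()),
        "mean_abs_cf_diff_b": float(b.mean()),
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "n": int(len(a)),
        "n_excluded": int((~ok).sum()),
    }


def cfdiff_selectivity_correlation(records=None, params: ModelParams | None = None,
                                   table: pd.DataFrame | None = None) -> dict:
    """Pearson correlation between signed CF_diff (octaves) and sweep
    selectivity across cells at the adult time point."""
    if table is None:
        if records is None:
            raise ValueError("provide records or a precomputed table")
        t_last = max(records[0].snapshots)
        table = population_table(records, params, times=[t_last], sweeps=True)
    sub = table.dropna(subset=["cf_diff_oct", "selectivity"])
    x = sub["cf_diff_oct"].to_numpy()
    y = sub["selectivity"].to_numpy()
    if len(x) < 3:
        raise ValueError("need >= 3 cells with defined CF and selectivity")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return {"pearson_r": float(r), "p_value": float(p), "n": int(len(x))}
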