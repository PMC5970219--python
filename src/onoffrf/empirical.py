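"""In-vivo-style analysis of spike-count FRAs and FM-sweep responses.

These are the analysis procedures applied to extracellular recordings from
auditory cortex (real or synthetic): frequency response areas built from
spike counts on a 25-frequency x 8-level tone grid, smoothed with a 3x3
pyramidal kernel; iso-response FRA edges at a 30% change from baseline;
characteristic frequency (CF), best frequency (BF) and bandwidth measured
from the edge mask; the direction selectivity index (DSI) for FM sweeps;
a multivariate linear model of DSI with per-predictor proportional
reduction of error (PRE); and the pharmacogenetic-response change metrics
(normalised response ratios, LFP onset amplitude, CF shifts in octaves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SpikeFRA",
    "SweepSpikes",
    "UnitProperties",
    "PYRAMIDAL_KERNEL",
    "smooth_fra",
    "fra_boundary",
    "characteristic_frequency",
    "best_frequency",
    "bandwidth_30db",
    "fra_overlap_percent",
    "dsi",
    "is_direction_selective",
    "fit_dsi_regression",
    "normalized_change",
    "lfp_on_amplitude",
    "cf_shift_octaves",
    "default_freq_axis",
    "default_level_axis",
    "DEFAULT_SPEEDS",
]

#: 25 tone frequencies, 7-56 kHz at 0.125-octave spacing.
def default_freq_axis() -> np.ndarray:
    return 7.0 * 2.0 ** (0.125 * np.arange(25))

#: 8 sound levels, 10-80 dB SPL in 10-dB steps.
def default_level_axis() -> np.ndarray:
    return np.arange(10.0, 81.0, 10.0)

#: FM sweep speeds in oct/s; each is presented in both directions
#: (12 velocities in total).
DEFAULT_SPEEDS = (2.2, 4.4, 8.8, 17.5, 35.0, 70.0)

PYRAMIDAL_KERNEL = np.array([[1.0, 2.0, 1.0],
                             [2.0, 4.0, 2.0],
                             [1.0, 2.0, 1.0]]) / 16.0


@dataclass
class SpikeFRA:
    """Spike counts on the tone grid for one unit.

    ``on_counts`` and ``off_counts`` have shape (n_freq, n_level,
    n_repeats): spikes in the 0-100 ms windows after tone onset and
    offset.  ``baseline_rate`` is the mean spike count in the 100 ms
    pre-stimulus window.
    """

    on_counts: np.ndarray
    off_counts: np.ndarray
    freq_axis: np.ndarray = field(default_factory=default_freq_axis)
    level_axis: np.ndarray = field(default_factory=default_level_axis)
    baseline_rate: float = 0.0
    spont_counts: np.ndarray | None = None   # per-repeat pre-stimulus counts

    def __post_init__(self):
        if self.spont_counts is not None:
            self.spont_counts = np.asarray(self.spont_counts)
            if self.baseline_rate == 0.0:
                self.baseline_rate = float(self.spont_counts.mean())
        self.on_counts = np.asarray(self.on_counts)
        self.off_counts = np.asarray(self.off_counts)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        self.level_axis = np.asarray(self.level_axis, dtype=float)
        for a in (self.on_counts, self.off_counts):
            if a.shape[:2] != (self.freq_axis.size, self.level_axis.size):
                raise ValueError("count array shape does not match the axes")
            if a.ndim != 3 or a.shape[2] < 1:
                raise ValueError("counts must be (freq, level, repeat) with >= 1 repeat")
            if np.any(a < 0):
                raise ValueError("spike counts must be non-negative")
        if np.any(np.diff(self.freq_axis) <= 0) or np.any(np.diff(self.level_axis) <= 0):
            raise ValueError("axes must be strictly increasing")

    def mean_surface(self, which: str = "on") -> np.ndarray:
        a = self.on_counts if which == "on" else self.off_counts
        return a.mean(axis=2)


@dataclass
class SweepSpikes:
    """Per-(speed, direction, repeat) spike counts for FM sweeps.

    ``counts`` maps (speed, direction) -> repeat array, with direction in
    {"UP", "DOWN"}; the counting window runs from sound onset to 100 ms
    after offset.
    """

    counts: dict
    speeds: tuple = DEFAULT_SPEEDS

    def repeats(self, speed: float, direction: str) -> np.ndarray:
        return np.asarray(self.counts[(speed, direction)], dtype=float)


@dataclass
class UnitProperties:
    """The ten DSI-regression predictors plus the response variable."""

    on_rate_increase: float
    off_rate_increase: float
    fano_on: float
    fano_off: float
    spont_rate: float
    fano_spont: float
    bw_on: float
    bw_off: float
    overlap_pct: float
    cf_diff_oct: float
    dsi_low: float

    PREDICTORS = ("on_rate_increase", "off_rate_increase", "fano_on",
                  "fano_off", "spont_rate", "fano_spont", "bw_on", "bw_off",
                  "overlap_pct", "cf_diff_oct")

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in (*self.PREDICTORS, "dsi_low")}


# --------------------------------------------------------------------- #
# tabular IO (the CSV schemas shared with the synthetic generator)
# --------------------------------------------------------------------- #

def spike_fra_from_frame(df: pd.DataFrame) -> SpikeFRA:
    """Build a SpikeFRA from a long tone table (one unit).

    Expected columns: freq_hz, level_db, repeat, on_count, off_count,
    baseline_count.
    """
    freqs = np.sort(df["freq_hz"].unique()) / 1000.0
    levels = np.sort(df["level_db"].unique())
    reps = np.sort(df["repeat"].unique())
    shape = (freqs.size, levels.size, reps.size)
    on = np.zeros(shape, dtype=int)
    off = np.zeros(shape, dtype=int)
    fi = {f: i for i, f in enumerate(freqs * 1000.0)}
    li = {l: j for j, l in enumerate(levels)}
    ri = {r: k for k, r in enumerate(reps)}
    for row in df.itertuples(index=False):
        i, j, k = fi[row.freq_hz], li[row.level_db], ri[row.repeat]
        on[i, j, k] = row.on_count
        off[i, j, k] = row.off_count
    # every presentation carries its own pre-stimulus baseline window
    return SpikeFRA(on, off, freqs, levels,
                    spont_counts=df["baseline_count"].to_numpy())


def sweep_spikes_from_frame(df: pd.DataFrame) -> SweepSpikes:
    """Build SweepSpikes from a long sweep table (one unit).

    Expected columns: velocity (signed oct/s), direction, repeat, count.
    """
    counts = {}
    for (speed, direction), grp in df.groupby([df["velocity"].abs(), "direction"]):
        counts[(float(speed), str(direction))] = (
            grp.sort_values("repeat")["count"].to_numpy())
    speeds = tuple(sorted({s for s, _ in counts}))
    return SweepSpikes(counts, speeds)


# --------------------------------------------------------------------- #
# FRA processing
# --------------------------------------------------------------------- #

def smooth_fra(raw: np.ndarray) -> np.ndarray:
    """Smooth a mean-count surface with the 3x3 pyramidal kernel.

    At edges the kernel is renormalised over in-bounds taps, so a constant
    surface is left exactly unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a 2-D (freq x level) surface")
    from scipy.signal import convolve2d
    num = convolve2d(raw, PYRAMIDAL_KERNEL, mode="same")
    den = convolve2d(np.ones_like(raw), PYRAMIDAL_KERNEL, mode="same")
    return num / den


def fra_boundary(smoothed: np.ndarray, baseline: float) -> np.ndarray:
    """Mask of grid cells with a defined response: >= 30% above baseline.

    When the baseline is zero the threshold falls back to 30% of the
    surface maximum.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if baseline < 0:
        raise ValueError("baseline must be non-negative")
    if baseline > 0:
        thresh = 1.3 * baseline
    else:
        thresh = 0.3 * smoothed.max()
        if thresh <= 0:
            return np.zeros_like(smoothed, dtype=bool)
    return smoothed >= thresh


def characteristic_frequency(mask: np.ndarray, freq_axis: np.ndarray,
                             level_axis: np.ndarray,
                             smoothed: np.ndarray | None = None) -> float:
    """CF in kHz: frequency with a defined response at the lowest level.

    At the lowest level containing any defined cell, the CF is the
    response-weighted geometric mean frequency of the defined cells
    (weights from ``smoothed`` when given, else uniform).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty FRA mask: no CF is defined (unit rejected)")
    level_idx = int(np.argmax(mask.any(axis=0)))
    rows = np.flatnonzero(mask[:, level_idx])
    if smoothed is not None:
        wts = np.asarray(smoothed, dtype=float)[rows, level_idx]
        if wts.sum() <= 0:
            wts = np.ones_like(wts)
    else:
        wts = np.ones(rows.size)
    log_f = np.log2(np.asarray(freq_axis, dtype=float)[rows])
    return float(2.0 ** (np.average(log_f, weights=wts)))


def best_frequency(smoothed: np.ndarray, freq_axis: np.ndarray,
                   level_axis: np.ndarray) -> tuple:
    """(kHz, dB) of the maximal response; ties resolve to the lowest level,
    then the lowest frequency."""
    s = np.asarray(smoothed, dtype=float)
    if s.size == 0:
        raise ValueError("empty surface")
    best = s.max()
    # iterate levels first so the lowest level wins ties
    for j in range(s.shape[1]):
        for i in range(s.shape[0]):
            if s[i, j] == best:
                return float(freq_axis[i]), float(level_axis[j])
    raise AssertionError("unreachable")


def bandwidth_30db(mask: np.ndarray, freq_axis: np.ndarray,
                   level_axis: np.ndarray) -> float | None:
    """Octave width of the defined region 30 dB above threshold.

    Threshold is the lowest level with any defined cell.  Returns None
    (undefined) when the target row lies outside the level grid or has no
    defined cells.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty FRA mask")
    level_axis = np.asarray(level_axis, dtype=float)
    thr_idx = int(np.argmax(mask.any(axis=0)))
    target = level_axis[thr_idx] + 30.0
    hits = np.flatnonzero(np.isclose(level_axis, target))
    if hits.size == 0:
        return None
    rows = np.flatnonzero(mask[:, hits[0]])
    if rows.size == 0:
        return None
    f = np.asarray(freq_axis, dtype=float)
    return float(np.log2(f[rows[-1]] / f[rows[0]]))


def fra_overlap_percent(mask_on: np.ndarray, mask_off: np.ndarray) -> float:
    """Percentage overlap of ON and OFF FRA regions.

    Defined as 100 x |intersection| / mean(|on|, |off|); identical masks
    give 100, disjoint masks 0.
    """
    a = np.asarray(mask_on, dtype=bool)
    b = np.asarray(mask_off, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    na, nb = a.sum(), b.sum()
    if na + nb == 0:
        raise ValueError("both masks empty: overlap undefined")
    return float(100.0 * np.logical_and(a, b).sum() / ((na + nb) / 2.0))


# --------------------------------------------------------------------- #
# sweeps
# --------------------------------------------------------------------- #

def dsi(spikes: SweepSpikes, speed: float) -> float:
    """Direction selectivity index (r_up - r_down)/(r_up + r_down) at one
    FM speed; 0 when neither direction evokes spikes."""
    r1 = spikes.repeats(speed, "UP").mean()
    r2 = spikes.repeats(speed, "DOWN").mean()
    if r1 + r2 == 0:
        return 0.0
    return float((r1 - r2) / (r1 + r2))


def low_speed_dsi(spikes: SweepSpikes,
                  speeds: tuple = (2.2, 4.4)) -> float:
    """Mean DSI over the two lowest FM speeds."""
    return float(np.mean([dsi(spikes, s) for s in speeds]))


def is_direction_selective(spikes: SweepSpikes,
                           threshold: float = 0.05) -> bool:
    """True when |mean DSI at the two lowest speeds (2.2, 4.4 oct/s)|
    is strictly above the criterion (0.05)."""
    for s in (2.2, 4.4):
        if (s, "UP") not in spikes.counts or (s, "DOWN") not in spikes.counts:
            raise ValueError(f"speed {s} oct/s missing from the sweep data")
    return abs(low_speed_dsi(spikes)) > threshold


# --------------------------------------------------------------------- #
# DSI regression with proportional reduction of error
# --------------------------------------------------------------------- #

def fit_dsi_regression(units, predictors=None, refit_truncated: bool = False) -> dict:
    """Linear model of DSI on z-scored unit properties, with per-predictor
    proportional reduction of error.

    The model is an ordinary least-squares fit of the low-speed DSI on the
    z-scored predictors (with intercept).  For each predictor the
    truncated prediction drops that predictor's term while keeping the
    full-model coefficients; PRE = (SSE_truncated - SSE_full)/SSE_full.
    ``refit_truncated=True`` refits the reduced model instead.

    Returns coefficients (on the z-scored scale), adjusted R-squared and
    the PRE per predictor.
    """
    predictors = list(predictors or UnitProperties.PREDICTORS)
    rows = [u.as_row() if isinstance(u, UnitProperties) else dict(u) for u in units]
    df = pd.DataFrame(rows)
    n = len(df)
    if n <= len(predictors) + 1:
        raise ValueError(
            f"need more units ({n}) than predictors + 1 ({len(predictors) + 1})"
        )
    X = df[predictors].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = [p for p, s in zip(predictors, sd) if s == 0]
        raise ValueError(f"zero-variance predictors: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # name the columns whose removal restores full rank
        bad = [p for i, p in enumerate(predictors)
               if np.linalg.matrix_rank(np.delete(Z, i, axis=1)) == rank]
        raise ValueError(f"collinear predictors: {bad}")
    y = df["dsi_low"].to_numpy(dtype=float)
    model = sm.OLS(y, sm.add_constant(pd.DataFrame(Z, columns=predictors))).fit()
    coefs = model.params[predictors]
    yhat_full = model.fittedvalues.to_numpy()
    sse_full = float(((y - yhat_full) ** 2).sum())
    pre = {}
    for i, pname in enumerate(predictors):
        if refit_truncated:
            keep = [q for q in predictors if q != pname]
            sub = sm.OLS(y, sm.add_constant(
                pd.DataFrame(Z[:, [predictors.index(q) for q in keep]],
                             columns=keep))).fit()
            sse_trunc = float(sub.ssr)
        else:
            yhat = yhat_full - coefs[pname] * Z[:, i]
            sse_trunc = float(((y - yhat) ** 2).sum())
        pre[pname] = (sse_trunc - sse_full) / sse_full if sse_full > 0 else np.inf
    return {
        "coefficients": coefs.to_dict(),
        "intercept": float(model.params["const"]),
        "p_values": model.pvalues[predictors].to_dict(),
        "adjusted_r2": float(model.rsquared_adj),
        "pre": pre,
        "n": n,
        "sse_full": sse_full,
    }


# --------------------------------------------------------------------- #
# pharmacogenetic-response metrics
# --------------------------------------------------------------------- #

def normalized_change(r_baseline, r_post, floor: float = 0.0) -> float:
    """Mean element-wise response ratio post/baseline.

    ``r_baseline`` and ``r_post`` are per-stimulus mean responses
    (restricted, by the caller, to stimuli inside the baseline FRA edges).
    Elements with baseline <= ``floor`` are excluded; a value above 1
    denotes increased activity in the post period.
    """
    r1 = np.asarray(r_baseline, dtype=float)
    r2 = np.asarray(r_post, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("response vectors must share a shape")
    keep = r1 > floor
    if not keep.any():
        raise ValueError("all elements excluded: change metric undefined")
    return float(np.mean(r2[keep] / r1[keep]))


def baseline_activity_ratio(s1: float, s2: float, min_spikes: float = 1.0):
    """S2/S1 change in baseline multi-unit activity; None (unit excluded)
    when the baseline mean spike count S1 is below ``min_spikes``."""
    if s1 < min_spikes:
        return None
    return float(s2 / s1)


def lfp_on_amplitude(trace: np.ndarray, sample_rate_hz: float,
                     window_ms: tuple = (0.0, 300.0)) -> float:
    """Evoked LFP amplitude: global minimum in the response window
    (deflections are negative-going).

    ``trace`` is sampled voltage starting at sound onset.
    """
    trace = np.asarray(trace, dtype=float)
    i0 = int(round(window_ms[0] * 1e-3 * sample_rate_hz))
    i1 = int(round(window_ms[1] * 1e-3 * sample_rate_hz))
    if i0 >= i1 or i1 > trace.size:
        raise ValueError("response window empty or outside the trace")
    return float(trace[i0:i1].min())


def cf_shift_octaves(cf1: float, cf2: float) -> float:
    """Octave shift log2(cf2/cf1) between two characteristic frequencies."""
    if cf1 <= 0 or cf2 <= 0:
        raise ValueError("CFs must be positive")
    return float(np.log2(cf2 / cf1))


# --------------------------------------------------------------------- #
# unit-level property extraction
# --------------------------------------------------------------------- #

def _fano(counts: np.ndarray) -> float:
    m = counts.mean()
    return float(counts.var(ddof=0) / m) if m > 0 else 0.0


def unit_properties(fra: SpikeFRA, sweeps: SweepSpikes,
                    probe_level_db: float = 60.0) -> UnitProperties | None:
    """Compute the ten regression predictors and low-speed DSI of one unit.

    Returns None when either FRA has no defined edge mask (units without
    both ON and OFF RFs are rejected) or a bandwidth is undefined.
    Rate increases and Fano factors are taken at the (CF, probe level)
    grid point; Fano factors are variance/mean of the repeat counts.
    """
    sm_on = smooth_fra(fra.mean_surface("on"))
    sm_off = smooth_fra(fra.mean_surface("off"))
    mask_on = fra_boundary(sm_on, fra.baseline_rate)
    mask_off = fra_boundary(sm_off, fra.baseline_rate)
    if not (mask_on.any() and mask_off.any()):
        return None
    cf_on = characteristic_frequency(mask_on, fra.freq_axis, fra.level_axis, sm_on)
    cf_off = characteristic_frequency(mask_off, fra.freq_axis, fra.level_axis, sm_off)
    bw_on = bandwidth_30db(mask_on, fra.freq_axis, fra.level_axis)
    bw_off = bandwidth_30db(mask_off, fra.freq_axis, fra.level_axis)
    if bw_on is None or bw_off is None:
        return None
    li = int(np.argmin(np.abs(fra.level_axis - probe_level_db)))
    fi_on = int(np.argmin(np.abs(np.log2(fra.freq_axis / cf_on))))
    fi_off = int(np.argmin(np.abs(np.log2(fra.freq_axis / cf_off))))
    on_counts = fra.on_counts[fi_on, li]
    off_counts = fra.off_counts[fi_off, li]
    spont = fra.baseline_rate
    return UnitProperties(
        on_rate_increase=float(on_counts.mean() - spont),
        off_rate_increase=float(off_counts.mean() - spont),
        fano_on=_fano(on_counts),
        fano_off=_fano(off_counts),
        spont_rate=float(spont),
        fano_spont=_fano(fra.spont_counts) if fra.spont_counts is not None else 0.0,
        bw_on=float(bw_on),
        bw_off=float(bw_off),
        overlap_pct=fra_overlap_percent(mask_on, mask_off),
        cf_diff_oct=cf_shift_octaves(cf_off, cf_on),
        dsi_low=low_speed_dsi(sweeps),
    )
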