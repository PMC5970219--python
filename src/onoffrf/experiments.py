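"""Named experiments: population runs behind the headline model figures.

Thin drivers that tie the simulation, probing and statistics together:

* ``divergence_experiment`` — the developmental divergence of ON/OFF CFs
  (hearing onset vs young vs adult, with KS tests);
* ``alternation_experiment`` — independent ON/OFF sequences vs the
  natural alternating condition;
* ``sweep_selectivity_experiment`` — CF-difference vs FM-sweep
  selectivity correlations for the full and the excitation-only model.

The sweep-selectivity axis used in the correlation is oriented so that
DOWN-preference is positive (descending-sweep preference grows as the ON
CF falls below the OFF CF), hence the reported correlations are negative;
the DSI itself (UP-positive) is in the tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import population_divergence_stats, population_table
from .params import ModelParams
from .simulate import run_population

__all__ = [
    "divergence_experiment",
    "alternation_experiment",
    "sweep_selectivity_experiment",
]


def divergence_experiment(params: ModelParams | None = None, n_cells: int = 100,
                          master_seed=0, condition: str = "single_channel",
                          records=None) -> dict:
    """Mean |CF_diff| at hearing onset / young / adult plus KS tests.

    With ``condition="scaling_only"`` this is the homeostatic-scaling
    control, where the distributions should be indistinguishable.
    """
    params = params or ModelParams()
    if records is None:
        records = run_population(n_cells, params, condition, master_seed)
    times = [0, params.t_young, params.t_adult]
    table = population_table(records, params, times=times)
    means = {t: float(table[table.time == t]["cf_diff_oct"].abs().mean())
             for t in times}
    out = {
        "condition": condition,
        "n_cells": len(records),
        "mean_abs_cf_diff": {"hearing_onset": means[0],
                             "young": means[params.t_young],
                             "adult": means[params.t_adult]},
        "young_vs_adult": population_divergence_stats(
            records, params.t_young, params.t_adult, params, table=table),
        "onset_vs_adult": population_divergence_stats(
            records, 0, params.t_adult, params, table=table),
        "table": table,
    }
    return out


def alternation_experiment(params: ModelParams | None = None, n_cells: int = 100,
                           master_seed=0, records_alternating=None,
                           records_independent=None) -> dict:
    """Adult |CF_diff| of independent-ON/OFF vs alternating sequences."""
    params = params or ModelParams()
    if records_alternating is None:
        records_alternating = run_population(n_cells, params, "single_channel",
                                             master_seed)
    if records_independent is None:
        records_independent = run_population(n_cells, params,
                                             "independent_on_off", master_seed)
    t = params.t_adult
    tab_a = population_table(records_alternating, params, times=[t])
    tab_i = population_table(records_independent, params, times=[t])
    a = tab_a["cf_diff_oct"].abs().dropna().to_numpy()
    b = tab_i["cf_diff_oct"].abs().dropna().to_numpy()
    ks = stats.ks_2samp(a, b)
    return {
        "mean_abs_cf_diff_alternating": float(a.mean()),
        "mean_abs_cf_diff_independent": float(b.mean()),
        "ks_statistic": float(ks.statistic),
        "ks_p_value": float(ks.pvalue),
        "n": (int(len(a)), int(len(b))),
    }


def _orient_down_positive(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["sweep_selectivity"] = -out["selectivity"]
    return out


def sweep_selectivity_experiment(params: ModelParams | None = None,
                                 n_cells: int = 100, master_seed=0,
                                 records_ex_in=None, records_ex_only=None,
                                 ) -> dict:
    """CF_diff vs sweep-selectivity correlations, full and Ex-only model.

    Selectivity is reported on the DOWN-positive axis, so both
    correlations come out negative when ON-above-OFF cells prefer
    ascending sweeps.
    """
    params = params or ModelParams()
    if records_ex_in is None:
        records_ex_in = run_population(n_cells, params, "single_channel",
                                       master_seed)
    if records_ex_only is None:
        records_ex_only = run_population(n_cells, params, "excitation_only",
                                         master_seed)
    out = {}
    for label, records in (("ex_in", records_ex_in),
                           ("ex_only", records_ex_only)):
        t = params.t_adult
        table = _orient_down_positive(
            population_table(records, params, times=[t], sweeps=True))
        sub = table.dropna(subset=["cf_diff_oct", "sweep_selectivity"])
        r, p = stats.pearsonr(sub["cf_diff_oct"], sub["sweep_selectivity"])
        out[label] = {"pearson_r": float(r), "p_value": float(p),
                      "n": int(len(sub)), "table": table}
    return out
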