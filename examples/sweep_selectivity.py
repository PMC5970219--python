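"""ON/OFF receptive-field arrangement predicts FM-sweep direction selectivity.

Develops a small adult population (20 cells; the study scale is 100),
probes each cell with ascending and descending stepwise frequency sweeps,
and correlates the signed ON-minus-OFF CF difference with the sweep
selectivity index across cells, for the full model and for the model with
evoked inhibition removed.
"""

from onoffrf import ModelParams
from onoffrf.experiments import sweep_selectivity_experiment

params = ModelParams()
res = sweep_selectivity_experiment(params, n_cells=20, master_seed=0)

for label, name in (("ex_in", "excitation + inhibition"),
                    ("ex_only", "excitation only")):
    r = res[label]
    print(f"{name}: r = {r['pearson_r']:+.3f}  (p = {r['p_value']:.2e},"
          f" n = {r['n']})")

print()
print("The selectivity axis is oriented with descending-sweep preference")
print("positive, so the correlation is negative: cells whose ON field sits")
print("above their OFF field respond more to ascending sweeps (the sweep")
print("leaves the OFF-preferred band just as it enters the ON-preferred")
print("one, and the coincident drive summates above threshold).")
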