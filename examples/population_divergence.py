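"""Population-level divergence of ON/OFF receptive fields.

Simulates a small population (20 cells; the full study uses 100) through
both developmental phases, then compares the distribution of absolute
ON/OFF CF differences between the young (t = 1,500) and adult
(t = 100,000) stages with a two-sample Kolmogorov-Smirnov test, and runs
the homeostatic-scaling control in which the divergence is absent.
"""

from onoffrf import ModelParams
from onoffrf.experiments import divergence_experiment

params = ModelParams()
res = divergence_experiment(params, n_cells=20, master_seed=0)
m = res["mean_abs_cf_diff"]
print("single-channel condition (Hebbian learning):")
print(f"  mean |CF_diff| (oct): hearing onset {m['hearing_onset']:.3f}"
      f" -> young {m['young']:.3f} -> adult {m['adult']:.3f}")
ks = res["young_vs_adult"]
print(f"  young vs adult KS: D = {ks['ks_statistic']:.3f}, p = {ks['ks_p_value']:.2e}")

ctrl = divergence_experiment(params, n_cells=20, master_seed=0,
                             condition="scaling_only")
mc = ctrl["mean_abs_cf_diff"]
ksc = ctrl["onset_vs_adult"]
print("synaptic-scaling control (no Hebbian learning):")
print(f"  mean |CF_diff| (oct): hearing onset {mc['hearing_onset']:.3f}"
      f" -> adult {mc['adult']:.3f}")
print(f"  onset vs adult KS p = {ksc['ks_p_value']:.2f}")
print()
print("Hebbian learning turns matched ON/OFF fields into diverged ones (at")
print("the full 100-cell scale the young/adult KS test rejects clearly);")
print("uniform multiplicative scaling preserves weight ratios, so the")
print("control's CF differences do not change at all.")
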