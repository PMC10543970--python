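"""Train the fed-batch biomass soft sensor end-to-end and compare baselines.

Runs a scaled-down campaign (3 fed-batch training runs + 1 held-out run),
sweeps three training engines over a restricted hidden-node grid, selects
the minimum-RMSE network and evaluates it on the held-out run against the
simulator's ground-truth biomass, alongside the pruned multiple-linear-
regression baseline and the calibrated turbidity-probe estimate.
"""

from fermsense import CampaignConfig, PipelineConfig, run_campaign
from fermsense.ann import ENGINE_LABELS

config = PipelineConfig(
    campaign=CampaignConfig(n_batch=0, n_fedbatch=4),
    nodes=(4, 6, 8),
    restarts=3,
)
report = run_campaign(config, seed=1)
task = report["tasks"]["fedbatch_biomass"]
sel = task["selected"]

print(f"selected model : {ENGINE_LABELS[sel['engine']]}, "
      f"{sel['n_hidden']} hidden nodes")
print(f"fit on pooled training runs : RMSE {sel['rmse']:.3f} g/L, "
      f"R2 {sel['r2']:.3f}")
h = task["holdout_vs_truth"]
m = task["mlr"]["holdout_vs_truth"]
p = task["tcd_probe_vs_truth"]
print(f"holdout run, ANN        : RMSE {h['rmse']:.3f} g/L, R2 {h['r2']:.4f}")
print(f"holdout run, MLR        : RMSE {m['rmse']:.3f} g/L, R2 {m['r2']:.4f}")
print(f"holdout run, TCD probe  : RMSE {p['rmse']:.3f} g/L, R2 {p['r2']:.4f}")
print(
    "\nThe neural soft sensor tracks the unseen run's biomass more closely\n"
    "than the linear baseline, which cannot absorb the turbidity probe's\n"
    "saturation or the volume dependence of the fed-batch channels."
)
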