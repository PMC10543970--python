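"""Off-gas analysis of one batch run: OUR, CER and RQ.

Simulates a batch cultivation, reconciles the gas channels with the
median + moving-average filter, and derives the volumetric oxygen uptake
rate, carbon-dioxide evolution rate and the molar respiratory quotient.
"""

import numpy as np

from fermsense import (
    CAMPAIGN_MEDIA,
    SimulatorParams,
    compute_cer,
    compute_our,
    compute_rq,
    reconcile,
    simulate_batch,
)

params = SimulatorParams()
series, _ = simulate_batch(CAMPAIGN_MEDIA[1], params, 24.0, seed=1)
rec = reconcile(series, ["o2_out_pct", "co2_out_pct"])

our = compute_our(rec, params.gas)
cer = compute_cer(rec, params.gas)
rq = compute_rq(our, cer, params.gas)

t = rec.frame.time_h.to_numpy()
i = int(np.argmax(our))
print(f"peak OUR  {our[i]:.4f} g O2/L/h at t = {t[i]:.1f} h")
print(f"peak CER  {cer.max():.4f} g CO2/L/h")
print(f"median RQ {np.nanmedian(rq):.3f} (mol CO2 per mol O2)")
print(
    "\nRespiration peaks mid-exponential phase; the near-constant RQ just\n"
    "above 1 reflects the fixed stoichiometric coupling of O2 use and CO2\n"
    "evolution to growth in this organism model."
)
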