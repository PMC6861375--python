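"""Differential drive: rate readout at low g_ks, phase readout at high g_ks.

Twenty excitatory neurons receive an extra offset current on top of the
common DC pattern.  At g_ks = 0 the subset simply fires faster (dfreq); at
g_ks = 1.5 the network bursts rhythmically and the subset instead fires at
an earlier phase of each population cycle (dphase, measured against the
Gaussian-smoothed population-rate peaks).

Runs the full 7 s protocol on a 375-neuron network at three offsets
(a few minutes on one CPU).
"""

import numpy as np

import ratephase as rp

df = rp.run_offset_experiment(offsets=np.array([0.0, 0.975, 1.95]),
                              master_seed=1)
print(df.to_string(index=False))
rho = rp.offset_correlations(df)
print()
print(f"Spearman(dfreq, offset) at g_ks=0.0 : {rho['rho_dfreq']:+.2f}")
print(f"Spearman(dphase, offset) at g_ks=1.5: {rho['rho_dphase']:+.2f}")
print()
print("The same input difference is expressed as a rate difference in the")
print("high-ACh state and as a phase advance (negative dphase) in the")
print("low-ACh bursting state.")
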