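"""Phase-coherence and burst metrics on surrogate rasters.

Demonstrates the boundary behaviour of the mean phase coherence (MPC) and
the population-burst detector on rasters with known structure.
"""

import numpy as np

import ratephase as rp
from ratephase.metrics import burst_order_similarity, detect_bursts, pairwise_phase
from ratephase.synth import RasterSpec, locked_raster, poisson_raster

# two periodic trains, fixed quarter-period lag -> perfect coherence
locked = locked_raster(RasterSpec(n_neurons=2, rates=10.0, period=100.0,
                                  lags=np.array([0.0, 25.0]), duration=5000.0))
rel = pairwise_phase(locked, 1, 0)
print(f"periodic, lag P/4 : MPC = {rel.coherence:.3f}, "
      f"mean phase = {rel.mean_phase:.3f} rad (pi/2 = {np.pi/2:.3f})")

# independent Poisson trains -> coherence at chance level ~ 1/sqrt(T)
noisy = poisson_raster(RasterSpec(n_neurons=2, rates=20.0, duration=200_000.0,
                                  seed=0))
rel = pairwise_phase(noisy, 0, 1)
print(f"independent Poisson: MPC = {rel.coherence:.4f} "
      f"(chance bound 3/sqrt(T) = {3/np.sqrt(rel.n_samples):.4f})")

# a jittered synchronous population -> bursts with a reproducible order
r = locked_raster(RasterSpec(n_neurons=50, rates=10.0, period=100.0,
                             lags=np.linspace(0.0, 12.0, 50), jitter=1.0,
                             duration=3000.0, seed=3))
bursts = detect_bursts(r)
rho = burst_order_similarity(bursts.orders[0], bursts.first_times[0],
                             bursts.orders[1], bursts.first_times[1])
print(f"locked population : {len(bursts.orders)} bursts detected; "
      f"firing-order correlation between bursts 1 and 2 = {rho:.3f}")

print()
print("MPC is 1 for perfectly locked trains, ~0 for unrelated ones; burst")
print("windows expose the within-cycle firing order that phase coding uses.")
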