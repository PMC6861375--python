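"""Surrogate spike rasters with known ground truth.

Every analysis routine is testable without running the simulator: Poisson
rasters (no phase structure, controlled rates), phase-locked rasters
(global period, per-neuron lags, Gaussian jitter), and grouped cohorts in
which either the rate vector or the lag vector is a group-level property —
the planted structure the network-specificity score must recover.

These are statistical surrogates only; they make no attempt at
biophysical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import SpikeRaster

__all__ = ["RasterSpec", "poisson_raster", "locked_raster", "grouped_cohort"]


@dataclass
class RasterSpec:
    """Recipe for a surrogate raster.

    ``rates`` (Hz) may be a scalar or per-neuron array.  A phase-locked
    raster is requested by setting ``period`` (ms) and per-neuron ``lags``
    (ms, within one period); ``jitter`` is the Gaussian spike-time sd (ms),
    truncated at +/- 0.45 period so the within-cycle order is preserved at
    small sd.
    """

    n_neurons: int
    rates: float | np.ndarray = 10.0
    period: float | None = None
    lags: np.ndarray | None = None
    jitter: float = 0.0
    duration: float = 5000.0
    seed: int = 0
    n_inhibitory: int = 0  # trailing neurons labelled inhibitory

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rates) < 0):
            raise ValueError("rates must be non-negative")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        if self.lags is not None:
            self.lags = np.asarray(self.lags, dtype=float)
            if self.period is None or np.any(np.abs(self.lags) >= self.period):
                raise ValueError("lags must lie within one period")

    def labels(self) -> np.ndarray:
        lab = np.ones(self.n_neurons, dtype=bool)
        if self.n_inhibitory:
            lab[-self.n_inhibitory:] = False
        return lab


def poisson_raster(spec: RasterSpec) -> SpikeRaster:
    """Independent homogeneous Poisson trains at the target rates."""
    if spec.period is not None:
        raise ValueError("poisson_raster requires no phase-lock structure")
    rng = np.random.default_rng(spec.seed)
    rates = np.broadcast_to(np.asarray(spec.rates, dtype=float), (spec.n_neurons,))
    trains = []
    for r in rates:
        if r == 0:
            trains.append(np.empty(0))
            continue
        n_exp = int(r * spec.duration / 1000.0 * 1.5 + 30)
        gaps = rng.exponential(1000.0 / r, size=n_exp)
        t = np.cumsum(gaps)
        while t.size and t[-1] < spec.duration:  # rare top-up
            extra = np.cumsum(rng.exponential(1000.0 / r, size=n_exp)) + t[-1]
            t = np.concatenate([t, extra])
        trains.append(t[t < spec.duration])
    return SpikeRaster(spikes=trains, ei_labels=spec.labels(),
                       duration=spec.duration, meta={"kind": "poisson",
                                                     "seed": spec.seed})


def locked_raster(spec: RasterSpec) -> SpikeRaster:
    """Periodic raster: neuron n fires near k P + lag_n with Gaussian jitter."""
    if spec.period is None:
        raise ValueError("locked_raster requires a global period")
    p = float(spec.period)
    lags = spec.lags if spec.lags is not None else np.zeros(spec.n_neurons)
    if lags.size != spec.n_neurons:
        raise ValueError("one lag per neuron required")
    rng = np.random.default_rng(spec.seed)
    n_cycles = int(spec.duration / p) + 2
    base = np.arange(n_cycles) * p
    cut = 0.45 * p
    trains = []
    for lag in lags:
        noise = rng.normal(0.0, spec.jitter, size=n_cycles) if spec.jitter else 0.0
        t = base + lag + np.clip(noise, -cut, cut)
        t = np.unique(t[(t >= 0) & (t < spec.duration)])
        trains.append(t)
    return SpikeRaster(spikes=trains, ei_labels=spec.labels(),
                       duration=spec.duration,
                       meta={"kind": "locked", "period": p, "seed": spec.seed})


def grouped_cohort(
    n_groups: int,
    runs_per_group: int,
    structure: str = "rate",
    effect: float = 1.0,
    seed: int = 0,
    n_neurons: int = 60,
    duration: float = 5000.0,
    base_rate: float = 10.0,
    period: float = 100.0,
    jitter: float = 3.0,
) -> tuple[list[SpikeRaster], np.ndarray]:
    """Labelled cohort with a group-level rate or phase signature.

    ``structure="rate"``: each group owns a target-rate vector
    ``base_rate * (1 + effect u)``, u ~ U(-0.5, 0.5) per neuron, and each
    run is an independent Poisson raster at those rates.
    ``structure="phase"``: each group owns a lag vector spanning
    ``effect * period/2`` and runs re-jitter the spike times.  ``effect=0``
    removes the group signature entirely (the null cohort).

    Returns (rasters, group labels).
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if structure not in ("rate", "phase"):
        raise ValueError("structure must be 'rate' or 'phase'")
    rng = np.random.default_rng(seed)
    rasters: list[SpikeRaster] = []
    labels = np.repeat(np.arange(n_groups), runs_per_group)
    for g in range(n_groups):
        if structure == "rate":
            u = rng.uniform(-0.5, 0.5, size=n_neurons)
            rates = np.clip(base_rate * (1.0 + effect * u), 0.0, None)
        else:
            lags = effect * rng.uniform(0.0, period / 2.0, size=n_neurons)
        for r in range(runs_per_group):
            run_seed = int(rng.integers(0, 2**31 - 1))
            if structure == "rate":
                spec = RasterSpec(n_neurons=n_neurons, rates=rates,
                                  duration=duration, seed=run_seed)
                rasters.append(poisson_raster(spec))
            else:
                spec = RasterSpec(n_neurons=n_neurons, rates=1000.0 / period,
                                  period=period, lags=lags, jitter=jitter,
                                  duration=duration, seed=run_seed)
                rasters.append(locked_raster(spec))
    return rasters, labels
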