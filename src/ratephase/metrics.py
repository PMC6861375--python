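"""Raster-level statistics: rates, pairwise phase, bursts, similarity, NS.

The two feature families are

* **frequency** — per-neuron firing rates over the analysis window, with
  the across-neuron coefficient of variation (COV) as the bandwidth of the
  rate code; and
* **phase** — for each excitatory neuron, the circular mean phase and the
  mean phase coherence (MPC) of its spikes relative to a reference
  inhibitory neuron.  The phase of spike k of neuron i inside the firing
  cycle of neuron j is ``phi = 2 pi (t_i^k - t_j^-)/(t_j^+ - t_j^-)``, and
  the coherence is the modulus of the mean complex phase vector, 1 for
  perfect locking and ~0 for unrelated trains.  Pairs qualify only when
  both neurons fired at least ``min_spikes`` (default 30) spikes.

Run-to-run similarity of a feature and the network-specificity score NS
(within-group vs between-group mean similarity, halved) quantify how much
of the firing pattern is attributable to the network realization or input
pattern that produced it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .raster import SpikeRaster

__all__ = [
    "FrequencyVector",
    "PhaseRelation",
    "MPCSummary",
    "BurstSet",
    "SimilarityMatrix",
    "NSScore",
    "firing_rates",
    "pairwise_phase",
    "mpc_summary",
    "smoothed_population_rate",
    "detect_bursts",
    "burst_order_similarity",
    "feature_similarity",
    "network_similarity_score",
    "phase_embedding",
    "scramble_features",
]

MIN_SPIKES = 30  # pair-qualification threshold over the analysis window


# --------------------------------------------------------------------- rates
@dataclass
class FrequencyVector:
    rates: np.ndarray  # Hz per neuron
    cov: float         # std/mean across neurons (nan if silent)


def firing_rates(
    raster: SpikeRaster, window: tuple[float, float] | None = None
) -> FrequencyVector:
    """Per-neuron rates (Hz) over ``window`` and their across-neuron COV."""
    lo, hi = raster.window(window)
    rates = raster.counts((lo, hi)) / ((hi - lo) / 1000.0)
    mean = rates.mean() if rates.size else 0.0
    cov = float(rates.std() / mean) if mean > 0 else float("nan")
    return FrequencyVector(rates=rates, cov=cov)


# --------------------------------------------------------------------- phase
@dataclass
class PhaseRelation:
    """Phases of neuron i's spikes within neuron j's firing cycles."""

    phases: np.ndarray      # radians in [0, 2 pi)
    mean_phase: float       # circular mean, radians
    coherence: float        # modulus of the mean complex phase vector
    n_samples: int


def pairwise_phase(
    raster: SpikeRaster,
    i: int,
    j: int,
    window: tuple[float, float] | None = None,
    min_spikes: int = MIN_SPIKES,
) -> PhaseRelation | None:
    """Phase relation of neuron i relative to neuron j, or None if either
    fired fewer than ``min_spikes`` spikes in the window (excluded pair).

    Only spikes of i bracketed by two consecutive spikes of j contribute;
    the measure is not symmetric in (i, j).
    """
    ti = raster.spikes_in(i, window)
    tj = raster.spikes_in(j, window)
    if ti.size < min_spikes or tj.size < min_spikes:
        return None
    idx = np.searchsorted(tj, ti, side="right")
    ok = (idx >= 1) & (idx < tj.size)
    if not np.any(ok):
        return None
    tm = tj[idx[ok] - 1]
    tp = tj[idx[ok]]
    phases = 2.0 * np.pi * (ti[ok] - tm) / (tp - tm)
    z = np.exp(1j * phases).mean()
    return PhaseRelation(
        phases=phases,
        mean_phase=float(np.angle(z) % (2.0 * np.pi)),
        coherence=float(np.abs(z)),
        n_samples=int(phases.size),
    )


@dataclass
class MPCSummary:
    """Excitatory-population phase features against one inhibitory reference."""

    reference: int
    mean_phase: np.ndarray  # per excitatory neuron, nan where excluded
    coherence: np.ndarray   # per excitatory neuron, nan where excluded
    valid: np.ndarray       # qualifying-pair mask
    network_mpc: float      # mean coherence over qualifying pairs
    excitatory_ids: np.ndarray


def mpc_summary(
    raster: SpikeRaster,
    reference: int | None = None,
    window: tuple[float, float] | None = None,
    min_spikes: int = MIN_SPIKES,
) -> MPCSummary:
    """Phase of every qualifying excitatory neuron against an inhibitory
    reference; the network MPC is the average coherence over those pairs.

    The reference defaults to the lowest-index inhibitory neuron with at
    least ``min_spikes`` spikes; if the requested reference is too sparse
    the next qualifying inhibitory neuron is used (with a warning).
    """
    inh = raster.inhibitory
    if inh.size == 0:
        raise ValueError("raster has no inhibitory neurons")
    counts = raster.counts(window)
    candidates = [r for r in ([reference] if reference is not None else []) if r in inh]
    candidates += [r for r in inh if r not in candidates]
    ref = next((r for r in candidates if counts[r] >= min_spikes), None)
    if ref is None:
        raise ValueError("no inhibitory neuron reaches the spike threshold")
    if reference is not None and ref != reference:
        warnings.warn(
            f"reference neuron {reference} fired fewer than {min_spikes} spikes; "
            f"falling back to neuron {ref}"
        )
    exc = raster.excitatory
    mean_phase = np.full(exc.size, np.nan)
    coherence = np.full(exc.size, np.nan)
    for k, e in enumerate(exc):
        rel = pairwise_phase(raster, e, ref, window, min_spikes)
        if rel is not None:
            mean_phase[k] = rel.mean_phase
            coherence[k] = rel.coherence
    valid = ~np.isnan(coherence)
    mpc = float(np.nanmean(coherence)) if valid.any() else float("nan")
    return MPCSummary(
        reference=int(ref), mean_phase=mean_phase, coherence=coherence,
        valid=valid, network_mpc=mpc, excitatory_ids=exc,
    )


# -------------------------------------------------------------------- bursts
@dataclass
class BurstSet:
    """Population bursts: padded windows plus per-burst firing order."""

    intervals: np.ndarray          # (m, 2) start/stop ms, merged after padding
    orders: list                    # per burst: neuron ids sorted by first spike
    first_times: list               # per burst: matching first-spike times
    threshold: float                # convolved-signal threshold (neurons)


def smoothed_population_rate(
    raster: SpikeRaster,
    window: tuple[float, float] | None = None,
    bin_ms: float = 0.05,
    sigma2: float = 1.0,
    support: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed population spike count.

    Spikes of all neurons are binned at ``bin_ms`` and convolved with
    ``exp(-t^2/sigma2)`` evaluated on [-support, support] ms.  Returns
    (bin centres ms, smoothed signal); this is both the burst detector's
    input and the phase reference for the offset experiment.
    """
    lo, hi = raster.window(window)
    all_spikes = np.concatenate(
        [raster.spikes_in(i, (lo, hi)) for i in range(raster.n_neurons)]
    ) if raster.n_neurons else np.empty(0)
    edges = np.arange(lo, hi + bin_ms, bin_ms)
    counts, _ = np.histogram(all_spikes, bins=edges)
    tker = np.arange(-support, support + bin_ms, bin_ms)
    kernel = np.exp(-tker**2 / sigma2)
    smooth = signal.fftconvolve(counts.astype(float), kernel, mode="same")
    return 0.5 * (edges[:-1] + edges[1:]), smooth


def detect_bursts(
    raster: SpikeRaster,
    window: tuple[float, float] | None = None,
    bin_ms: float = 0.05,
    sigma2: float = 1.0,
    support: float = 10.0,
    threshold_frac: float = 0.1,
    pad: float = 10.0,
) -> BurstSet:
    """Threshold the Gaussian-smoothed population spike count.

    A burst is any contiguous stretch where the smoothed population count
    exceeds ``threshold_frac`` of the neuron count.  Bursts are padded by
    ``pad`` ms on each side (to capture the spikes that initiate them) and
    overlapping padded windows merged.
    """
    lo, hi = raster.window(window)
    thr = threshold_frac * raster.n_neurons
    centres, smooth = smoothed_population_rate(raster, (lo, hi), bin_ms, sigma2,
                                               support)
    if smooth.size == 0 or not np.any(smooth > 0):
        return BurstSet(np.empty((0, 2)), [], [], thr)
    edges = np.arange(lo, hi + bin_ms, bin_ms)
    above = smooth > thr
    if not above.any():
        return BurstSet(np.empty((0, 2)), [], [], thr)
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]
    t_start = edges[starts] - pad
    t_stop = edges[stops] + pad
    # merge overlapping padded windows
    merged = [[t_start[0], t_stop[0]]]
    for a, b in zip(t_start[1:], t_stop[1:]):
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    intervals = np.clip(np.asarray(merged), lo, hi)
    orders, firsts = [], []
    for a, b in intervals:
        ids, times = [], []
        for i in range(raster.n_neurons):
            s = raster.spikes[i]
            k = np.searchsorted(s, a, side="left")
            if k < s.size and s[k] < b:
                ids.append(i)
                times.append(s[k])
        ids = np.asarray(ids, dtype=int)
        times = np.asarray(times)
        # sort by first-spike time; ties broken by neuron index (stable on
        # the pre-sorted id order)
        order = np.argsort(times, kind="stable")
        orders.append(ids[order])
        firsts.append(times[order])
    return BurstSet(intervals=intervals, orders=orders, first_times=firsts,
                    threshold=thr)


def burst_order_similarity(
    order_a: np.ndarray,
    times_a: np.ndarray,
    order_b: np.ndarray,
    times_b: np.ndarray,
    min_common: int = 3,
) -> float | None:
    """Spearman correlation of first-spike order over shared participants.

    Returns None when fewer than ``min_common`` neurons fired in both
    bursts (undefined marker).
    """
    common, ia, ib = np.intersect1d(order_a, order_b, return_indices=True)
    if common.size < min_common:
        return None
    rho = stats.spearmanr(times_a[ia], times_b[ib]).statistic
    return float(rho)


# ---------------------------------------------------------------- similarity
@dataclass
class SimilarityMatrix:
    """Pairwise run similarity S for one feature at one condition."""

    s: np.ndarray          # (runs, runs)
    groups: np.ndarray     # realization label per run
    mode: str
    feature: str = ""


def phase_embedding(mean_phases: np.ndarray) -> np.ndarray:
    """Complex embedding of circular mean phases: [cos, sin] concatenated.

    Comparing phases through this embedding avoids wrap-around artifacts;
    invalid (nan) phases stay nan in both halves.
    """
    return np.concatenate([np.cos(mean_phases), np.sin(mean_phases)], axis=-1)


def scramble_features(features: np.ndarray, seed: int | None = 0) -> np.ndarray:
    """Control: permute the neuron assignment independently within each run."""
    rng = np.random.default_rng(seed)
    out = np.array(features, dtype=float, copy=True)
    for r in range(out.shape[0]):
        out[r] = out[r, rng.permutation(out.shape[1])]
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return np.nan
    x, y = a[ok] - a[ok].mean(), b[ok] - b[ok].mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        return 0.0
    return float(x @ y / (nx * ny))


def feature_similarity(
    features: np.ndarray,
    groups: np.ndarray,
    mode: str = "pca",
    scramble: bool = False,
    seed: int | None = 0,
    feature_name: str = "",
) -> SimilarityMatrix:
    """Run-by-run similarity of per-neuron feature vectors.

    ``features`` is (runs, neurons); entries may be nan (excluded neurons).
    Modes:

    * ``"pca"`` (default) — vectors are mean-centred across runs and
      projected onto the leading principal axis of the cohort;
      ``S_ab = (x_a.v)(x_b.v) / (|x_a||x_b|)`` with the norms of the full
      centred vectors, i.e. the correlation of the runs' leading-component
      content.  The diagonal is 1 by definition.
    * ``"pearson"`` — plain Pearson correlation of the raw vectors over the
      neurons valid in both runs (sensitivity bypass of the PCA step).
    * ``"dot"`` — unnormalised product of leading-axis projections.

    ``scramble=True`` permutes the neuron assignment within each run first
    (the chance-level control).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (runs >= 2, neurons) feature matrix")
    groups = np.asarray(groups)
    if groups.size != x.shape[0]:
        raise ValueError("one group label per run required")
    if scramble:
        x = scramble_features(x, seed)
    n_runs = x.shape[0]
    s = np.full((n_runs, n_runs), np.nan)
    if mode == "pearson":
        for a in range(n_runs):
            s[a, a] = 1.0
            for b in range(a + 1, n_runs):
                s[a, b] = s[b, a] = _pearson(x[a], x[b])
    elif mode in ("pca", "dot"):
        common = np.all(np.isfinite(x), axis=0)
        if common.sum() < 2:
            raise ValueError("fewer than 2 neurons are valid in every run")
        xc = x[:, common] - x[:, common].mean(axis=0, keepdims=True)
        norms = np.linalg.norm(xc, axis=1)
        if np.allclose(xc, 0.0):
            proj = np.zeros(n_runs)
        else:
            _, _, vt = np.linalg.svd(xc, full_matrices=False)
            proj = xc @ vt[0]
        if mode == "dot":
            s = np.outer(proj, proj)
        else:
            safe = np.where(norms > 0, norms, 1.0)
            s = np.outer(proj / safe, proj / safe)
            np.fill_diagonal(s, 1.0)
    else:
        raise ValueError(f"unknown similarity mode {mode!r}")
    return SimilarityMatrix(s=s, groups=groups, mode=mode, feature=feature_name)


# ------------------------------------------------------------------ NS score
@dataclass
class NSScore:
    """Group specificity of a feature: within- vs between-group similarity."""

    group: object
    ns: float                    # (mean within - mean between) / divisor
    scale: float = 1.0           # COV (freq) or mean MPC (phase) of the group
    ns_scaled: float = field(default=np.nan)

    def __post_init__(self) -> None:
        if np.isnan(self.ns_scaled):
            self.ns_scaled = self.scale * self.ns


def network_similarity_score(
    sim: SimilarityMatrix,
    scales: dict | None = None,
    divisor: float = 2.0,
    squared: bool = False,
) -> list[NSScore]:
    """Per-realization NS: half the gap between the mean similarity of runs
    on the same realization and runs on different realizations.

    0 when all runs are equally similar regardless of grouping.  ``scales``
    optionally maps group label -> bandwidth factor (mean COV for the
    frequency feature, mean MPC for phase) for the scaled variant.
    ``squared=True`` applies the alternative reading of the score's
    normalisation (squaring the gap, sign lost).  Groups with fewer than
    two runs are skipped.
    """
    s, groups = sim.s, sim.groups
    out: list[NSScore] = []
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2:
            continue
        idx = np.flatnonzero(mask)
        other = np.flatnonzero(~mask)
        within = s[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        w = np.nanmean(within[iu])
        b = np.nanmean(s[np.ix_(idx, other)]) if other.size else np.nan
        gap = w - b
        ns = gap**2 if squared else gap / divisor
        scale = 1.0 if scales is None else float(scales.get(g, np.nan))
        out.append(NSScore(group=g, ns=float(ns), scale=scale))
    if not out:
        raise ValueError("no group with at least two runs")
    return out
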