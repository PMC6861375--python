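"""Orchestration of the four reference experiment designs.

* **structure-varying** — several network realizations, one fixed DC input
  pattern; the NS scores measure how much of the firing pattern encodes the
  wiring.
* **input-varying** — one fixed network, several DC patterns; NS measures
  input coding.
* **offset** — a fixed subset of excitatory neurons receives an extra
  constant current; the readout is the rate difference at low g_ks and the
  burst-phase difference at high g_ks.
* **robustness** — the structure/input designs re-run while scanning the
  noise rate or the excitatory coupling.

The default plan is deliberately small (5 realizations x 5 runs, 3 s of
model time) so a full design runs on a laptop; the reference scale
(20 x 50, 7 s) is a parameter choice away.  All seeds derive from one
master seed, so a plan re-run is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .netgen import (NoiseSpec, OffsetSpec, calibrate_mean_input,
                     generate_input_pattern, generate_network)
from .params import CellParams, SynapseParams, default_cell, default_synapse
from .raster import SpikeRaster
from .simulator import SimConfig, SimulationError, run_simulation

log = logging.getLogger(__name__)

__all__ = [
    "ExperimentPlan",
    "plan_to_yaml",
    "plan_from_yaml",
    "run_structure_experiment",
    "run_input_experiment",
    "run_offset_experiment",
    "offset_correlations",
    "burst_peak_times",
    "run_robustness_scan",
]


def _derive_seed(*parts: int) -> int:
    """Deterministic 31-bit seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


@dataclass
class ExperimentPlan:
    """Replicate counts, grids and seeds for one experiment design."""

    gks_grid: tuple = (0.0, 1.4)
    n_realizations: int = 5        # reference scale: 20
    runs_per_realization: int = 5  # reference scale: 50
    duration: float = 3000.0       # reference scale: 7000 ms
    analysis_window: float = 2000.0  # reference scale: final 5000 ms
    noise_rate: float = 1.0
    master_seed: int = 0
    n_e: int = 300
    n_i: int = 75
    similarity_mode: str = "pearson"
    recalibrate_per_gks: bool = True
    target_rate: float = 10.0
    cell: CellParams = field(default_factory=default_cell)
    synapse: SynapseParams = field(default_factory=default_synapse)

    def __post_init__(self) -> None:
        if self.n_realizations < 2 or self.runs_per_realization < 2:
            raise ValueError("NS needs >= 2 realizations and >= 2 runs each")

    @property
    def min_spikes(self) -> int:
        """Pair-qualification threshold, scaled with the analysis window."""
        return max(4, round(metrics.MIN_SPIKES * self.analysis_window / 5000.0))

    @property
    def window(self) -> tuple[float, float]:
        return (self.duration - self.analysis_window, self.duration)


_PLAN_SCALARS = (
    "n_realizations", "runs_per_realization", "duration", "analysis_window",
    "noise_rate", "master_seed", "n_e", "n_i", "similarity_mode",
    "recalibrate_per_gks", "target_rate",
)


def plan_to_yaml(plan: ExperimentPlan, path) -> None:
    """Persist a plan; cell/synapse constants stay in the versioned
    parameter file and are not duplicated here."""
    import yaml

    payload = {k: getattr(plan, k) for k in _PLAN_SCALARS}
    payload["gks_grid"] = [float(g) for g in plan.gks_grid]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def plan_from_yaml(path) -> ExperimentPlan:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["gks_grid"] = tuple(raw.get("gks_grid", (0.0, 1.4)))
    return ExperimentPlan(**raw)


def _calibration(plan: ExperimentPlan) -> dict[float, float]:
    out: dict[float, float] = {}
    base = None
    for g in plan.gks_grid:
        cell = plan.cell.with_gks(g if plan.recalibrate_per_gks else 0.0)
        if not plan.recalibrate_per_gks and base is not None:
            out[g] = base
            continue
        cur = calibrate_mean_input(cell, plan.target_rate)
        out[g] = cur
        base = cur
    return out


def _choose_reference(rasters: list[SpikeRaster], window, min_spikes: int) -> int:
    """One inhibitory reference id for the whole cohort at a given g_ks.

    The lowest-index inhibitory neuron qualifying in every run; if none
    qualifies everywhere, the one qualifying in the most runs.
    """
    inh = rasters[0].inhibitory
    qual = np.zeros(inh.size, dtype=int)
    for r in rasters:
        qual += r.counts(window)[inh] >= min_spikes
    full = np.flatnonzero(qual == len(rasters))
    if full.size:
        return int(inh[full[0]])
    return int(inh[np.argmax(qual)])


def _cohort_features(plan: ExperimentPlan, rasters, groups):
    """Per-run frequency and phase features plus the per-group scale factors."""
    window = plan.window
    ref = _choose_reference(rasters, window, plan.min_spikes)
    freq, phase, covs, mpcs = [], [], [], []
    for r in rasters:
        fv = metrics.firing_rates(r, window)
        freq.append(fv.rates)
        covs.append(fv.cov)
        try:
            mp = metrics.mpc_summary(r, reference=ref, window=window,
                                     min_spikes=plan.min_spikes)
            phase.append(mp.mean_phase)
            mpcs.append(mp.network_mpc)
        except ValueError:
            phase.append(np.full(r.excitatory.size, np.nan))
            mpcs.append(np.nan)
    freq = np.asarray(freq)
    phase = np.asarray(phase)
    covs = np.asarray(covs)
    mpcs = np.asarray(mpcs)
    groups = np.asarray(groups)
    scale_cov = {g: float(np.nanmean(covs[groups == g])) for g in np.unique(groups)}
    scale_mpc = {g: float(np.nanmean(mpcs[groups == g])) for g in np.unique(groups)}
    return freq, phase, scale_cov, scale_mpc, covs, mpcs


def _score_cohort(plan: ExperimentPlan, gks, rasters, groups, scan_value=np.nan):
    freq, phase, scale_cov, scale_mpc, covs, mpcs = _cohort_features(
        plan, rasters, groups
    )
    rows = []
    emb = metrics.phase_embedding(phase)
    for feature, x, scales in (
        ("freq", freq, scale_cov),
        ("phase", emb, scale_mpc),
    ):
        for scrambled in (False, True):
            try:
                sim = metrics.feature_similarity(
                    x, groups, mode=plan.similarity_mode, scramble=scrambled,
                    seed=_derive_seed(plan.master_seed, 5, int(scrambled)),
                    feature_name=feature,
                )
                scores = metrics.network_similarity_score(sim, scales=scales)
            except ValueError as err:
                log.warning("similarity failed (gks=%s, %s): %s", gks, feature, err)
                continue
            for sc in scores:
                rows.append(
                    dict(gks=gks, scan_value=scan_value, feature=feature,
                         realization=int(sc.group), scrambled=scrambled,
                         ns=sc.ns, ns_scaled=sc.ns_scaled, scale=sc.scale,
                         mean_cov=float(np.nanmean(covs)),
                         mean_mpc=float(np.nanmean(mpcs)))
                )
    return rows


def _simulate_design(
    plan: ExperimentPlan,
    vary: str,
    gks: float,
    current: float,
    noise_rate: float | None = None,
    w_e: float | None = None,
):
    """All (realization, run) rasters for one g_ks level of a design."""
    cell = plan.cell.with_gks(gks)
    syn = plan.synapse if w_e is None else replace(plan.synapse, w_e=w_e)
    rate = plan.noise_rate if noise_rate is None else noise_rate
    n_total = plan.n_e + plan.n_i
    fixed_net = generate_network(
        _derive_seed(plan.master_seed, 1, 0), plan.n_e, plan.n_i
    )
    fixed_pat = generate_input_pattern(
        _derive_seed(plan.master_seed, 2, 0), mean=current, n_neurons=n_total
    )
    rasters, groups = [], []
    for real in range(plan.n_realizations):
        if vary == "structure":
            net = generate_network(
                _derive_seed(plan.master_seed, 1, real + 1), plan.n_e, plan.n_i
            )
            pat = fixed_pat
        else:
            net = fixed_net
            pat = generate_input_pattern(
                _derive_seed(plan.master_seed, 2, real + 1),
                mean=current, n_neurons=n_total,
            )
        for run in range(plan.runs_per_realization):
            cfg = SimConfig(
                duration=plan.duration, analysis_window=plan.analysis_window,
                run_seed=_derive_seed(plan.master_seed, 3, real, run),
            )
            noise = NoiseSpec(rate=rate,
                              noise_seed=_derive_seed(plan.master_seed, 4, real, run))
            try:
                rasters.append(
                    run_simulation(net, pat, None, noise, cell, syn, cfg)
                )
                groups.append(real)
            except SimulationError as err:
                log.warning("run (%s, real=%d, run=%d) failed: %s",
                            gks, real, run, err)
    return rasters, np.asarray(groups)


def _run_design(plan: ExperimentPlan, vary: str) -> pd.DataFrame:
    calib = _calibration(plan)
    rows = []
    for gks in plan.gks_grid:
        rasters, groups = _simulate_design(plan, vary, gks, calib[gks])
        rows.extend(_score_cohort(plan, gks, rasters, groups))
    return pd.DataFrame(rows)


def run_structure_experiment(plan: ExperimentPlan) -> pd.DataFrame:
    """NS of frequency and phase vs g_ks with varying network structure.

    One row per (g_ks, feature, realization, scrambled flag): the NS score,
    its bandwidth-scaled variant (COV-scaled for frequency, MPC-scaled for
    phase) and the cohort's mean COV/MPC.
    """
    return _run_design(plan, "structure")


def run_input_experiment(plan: ExperimentPlan) -> pd.DataFrame:
    """Same as :func:`run_structure_experiment` with fixed structure and
    varying DC input patterns."""
    return _run_design(plan, "input")


# ------------------------------------------------------------------- offset
def burst_peak_times(
    raster: SpikeRaster, window=None
) -> np.ndarray:
    """Times of the smoothed population-rate maxima, one per detected burst."""
    bursts = metrics.detect_bursts(raster, window)
    centres, smooth = metrics.smoothed_population_rate(raster, window)
    peaks = []
    for a, b in bursts.intervals:
        m = (centres >= a) & (centres <= b)
        if m.any():
            peaks.append(centres[m][np.argmax(smooth[m])])
    return np.asarray(peaks)


def _burst_phase_gap(
    raster: SpikeRaster, subset: np.ndarray, window, min_spikes: int = 5
) -> float:
    """Circular mean burst phase of the subset minus the rest.

    The Gaussian-smoothed population rate defines the reference oscillator:
    its maxima form a reference event train, every excitatory spike
    bracketed by two consecutive maxima gets the usual cycle phase
    ``2 pi (t - t_peak^-)/(t_peak^+ - t_peak^-)``, each neuron is reduced
    to its circular mean phase vector, and the gap is the angle between the
    subset's and the remaining excitatory population's mean vectors.
    Negative = the subset leads.  nan when fewer than 4 bursts exist.
    """
    peaks = burst_peak_times(raster, window)
    if peaks.size < 4:
        return float("nan")
    subset = set(int(i) for i in subset)
    z_sub, z_rest = [], []
    for i in raster.excitatory:
        s = raster.spikes_in(int(i), window)
        if s.size < min_spikes:
            continue
        idx = np.searchsorted(peaks, s, side="right")
        ok = (idx >= 1) & (idx < peaks.size)
        if not ok.any():
            continue
        ph = 2.0 * np.pi * (s[ok] - peaks[idx[ok] - 1]) / (
            peaks[idx[ok]] - peaks[idx[ok] - 1]
        )
        z = np.exp(1j * ph).mean()
        (z_sub if int(i) in subset else z_rest).append(z)
    if not z_sub or not z_rest:
        return float("nan")
    return float(np.angle(np.mean(z_sub) / np.mean(z_rest)))


def run_offset_experiment(
    offsets: np.ndarray | None = None,
    gks_pair: tuple[float, float] = (0.0, 1.5),
    master_seed: int = 0,
    subset_size: int = 20,
    duration: float = 7000.0,
    analysis_window: float = 5000.0,
    noise_rate: float = 1.0,
    n_e: int = 300,
    n_i: int = 75,
    cell: CellParams | None = None,
    synapse: SynapseParams | None = None,
    target_rate: float = 10.0,
    recalibrate_per_gks: bool = True,
) -> pd.DataFrame:
    """Rate and burst-phase response of a driven excitatory subset.

    ``subset_size`` excitatory neurons receive an extra ``i_offset`` on top
    of the common DC pattern.  At the low conductance the readout is
    ``dfreq`` (mean subset rate minus mean rate of the other excitatory
    neurons); at the high conductance it is ``dphase``, the circular mean
    burst phase of the subset relative to the rest, measured against the
    Gaussian-smoothed population-rate peaks.  One row per (g_ks, offset).
    """
    if offsets is None:
        offsets = np.linspace(0.0, 1.95, 5)
    cell = cell if cell is not None else default_cell()
    synapse = synapse if synapse is not None else default_synapse()
    net = generate_network(_derive_seed(master_seed, 11), n_e, n_i)
    subset_seed = _derive_seed(master_seed, 12)
    rows = []
    base_current = calibrate_mean_input(cell.with_gks(min(gks_pair)), target_rate)
    for gks in gks_pair:
        c = cell.with_gks(gks)
        current = (calibrate_mean_input(c, target_rate)
                   if recalibrate_per_gks else base_current)
        pat = generate_input_pattern(_derive_seed(master_seed, 13),
                                     mean=current, n_neurons=n_e + n_i)
        for k, off in enumerate(np.asarray(offsets, dtype=float)):
            spec = OffsetSpec.draw(net, off, subset_seed, subset_size)
            cfg = SimConfig(duration=duration, analysis_window=analysis_window,
                            run_seed=_derive_seed(master_seed, 14, k))
            noise = NoiseSpec(rate=noise_rate,
                              noise_seed=_derive_seed(master_seed, 15, k))
            raster = run_simulation(net, pat, spec, noise, c, synapse, cfg)
            fv = metrics.firing_rates(raster, cfg.window)
            in_sub = np.zeros(raster.n_neurons, dtype=bool)
            in_sub[spec.subset] = True
            exc = raster.ei_labels
            dfreq = fv.rates[in_sub].mean() - fv.rates[exc & ~in_sub].mean()
            dphase = _burst_phase_gap(raster, spec.subset, cfg.window)
            rows.append(dict(gks=gks, i_offset=off, dfreq=float(dfreq),
                             dphase=dphase))
    return pd.DataFrame(rows)


def offset_correlations(result: pd.DataFrame) -> dict[str, float]:
    """Spearman correlations of dfreq (low g_ks) and dphase (high g_ks)
    against the offset current."""
    lo = result[result.gks == result.gks.min()]
    hi = result[result.gks == result.gks.max()]
    rho_f = stats.spearmanr(lo.i_offset, lo.dfreq).statistic
    hi_ok = hi.dropna(subset=["dphase"])
    rho_p = (stats.spearmanr(hi_ok.i_offset, hi_ok.dphase).statistic
             if len(hi_ok) >= 3 else float("nan"))
    return {"rho_dfreq": float(rho_f), "rho_dphase": float(rho_p)}


# --------------------------------------------------------------- robustness
def run_robustness_scan(
    plan: ExperimentPlan,
    scan: str = "coupling",
    values: np.ndarray | None = None,
    vary: str = "input",
) -> pd.DataFrame:
    """NS surfaces over (g_ks x noise rate) or (g_ks x excitatory coupling).

    ``scan='coupling'`` sweeps w_e (mS/cm^2, reference range 0 to 0.04);
    ``scan='noise'`` sweeps the forced-spike rate (Hz).
    """
    if scan not in ("coupling", "noise"):
        raise ValueError("scan must be 'coupling' or 'noise'")
    if values is None:
        values = (np.linspace(0.0, 0.04, 5) if scan == "coupling"
                  else np.array([0.0, 1.0, 5.0, 10.0]))
    calib = _calibration(plan)
    rows = []
    for gks in plan.gks_grid:
        for v in np.asarray(values, dtype=float):
            kw = {"w_e": v} if scan == "coupling" else {"noise_rate": v}
            rasters, groups = _simulate_design(plan, vary, gks, calib[gks], **kw)
            rows.extend(_score_cohort(plan, gks, rasters, groups, scan_value=v))
    df = pd.DataFrame(rows)
    df["scan"] = scan
    return df
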