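"""Single-neuron characterisation: f/I curve, phase response curve, SFA.

These are the protocols that establish the excitability switch of the Ks
cell: lowering the slow potassium conductance (high acetylcholine) gives a
Type 1 cell — continuous f/I onset, high gain, monophasic (all-advance)
PRC, negligible adaptation — while raising it gives a Type 2 cell with a
discontinuous onset, shallow gain, biphasic PRC and pronounced spike-
frequency adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netgen import calibrate_mean_input
from .params import CellParams
from .simulator import single_neuron_spikes

__all__ = [
    "FICurve", "PRCCurve", "SFAIndexGrid",
    "fi_curve", "measure_prc", "sfa_index", "sfa_burst", "sfa_grid",
]


@dataclass
class FICurve:
    """Steady firing rate vs injected constant current."""

    current: np.ndarray   # uA/cm^2, ascending
    rate: np.ndarray      # Hz
    onset_current: float  # first grid current with >= 2 steady spikes (nan if none)
    onset_rate: float     # rate at the onset grid point

    def mean_slope_above_onset(self) -> float:
        """Average finite-difference gain (Hz per uA/cm^2) above onset."""
        mask = self.current >= self.onset_current
        if mask.sum() < 2:
            return float("nan")
        return float(np.mean(np.diff(self.rate[mask]) / np.diff(self.current[mask])))


def fi_curve(
    cell: CellParams,
    i_grid: np.ndarray,
    sim_time: float = 3000.0,
    dt: float = 0.05,
) -> FICurve:
    """f/I curve of an isolated neuron.

    The steady rate at each current is counted over the last 60% of the
    run, discarding the onset transient.
    """
    i_grid = np.asarray(i_grid, dtype=float)
    if np.any(np.diff(i_grid) <= 0):
        raise ValueError("i_grid must be sorted ascending")
    t0 = 0.4 * sim_time
    rates = np.empty(i_grid.size)
    onset_i = float("nan")
    onset_r = float("nan")
    for k, cur in enumerate(i_grid):
        spk = single_neuron_spikes(cell, cur, duration=sim_time, dt=dt)
        n = int(np.count_nonzero(spk >= t0))
        rates[k] = n / ((sim_time - t0) / 1000.0)
        if np.isnan(onset_i) and n >= 2:
            onset_i = float(cur)
            onset_r = float(rates[k])
    return FICurve(current=i_grid, rate=rates, onset_current=onset_i,
                   onset_rate=onset_r)


@dataclass
class PRCCurve:
    """Normalised phase advance (+) / delay (-) vs perturbation phase."""

    phase: np.ndarray       # perturbation phases in [0, 1)
    response: np.ndarray    # (T0 - T_perturbed)/T0
    period: float           # unperturbed period, ms
    amplitude: float        # perturbation amplitude, uA/cm^2
    width: float            # perturbation width, ms


class NonPeriodicError(RuntimeError):
    """Baseline firing is not stably periodic (ISI CV above tolerance)."""


def _baseline(cell: CellParams, current: float, settle: float, dt: float):
    spk = single_neuron_spikes(cell, current, duration=settle + 600.0, dt=dt)
    late = spk[spk > settle]
    if late.size < 4:
        raise NonPeriodicError("too few baseline spikes after the settle time")
    isi = np.diff(late)
    if isi.std() / isi.mean() > 0.01:
        raise NonPeriodicError(
            f"baseline ISI CV {isi.std() / isi.mean():.3%} exceeds 1%"
        )
    return late[0], float(isi.mean())


def measure_prc(
    cell: CellParams,
    target_rate: float = 10.0,
    amplitude: float | None = None,
    width: float = 1.0,
    phase_grid: np.ndarray | None = None,
    settle: float = 2000.0,
    dt: float = 0.05,
) -> PRCCurve:
    """PRC by the direct perturbation protocol.

    The cell is driven to fire periodically at ``target_rate`` (current
    found by bisection), a brief depolarising square pulse is delivered at
    each phase of one late cycle, and the response is the normalised change
    of that cycle's period, positive for an advance.  When ``amplitude``
    is None the smallest pulse on a doubling ladder whose maximal response
    magnitude exceeds 0.5% is used ("small, brief and depolarising").
    """
    if phase_grid is None:
        phase_grid = np.arange(0.025, 1.0, 0.05)
    phase_grid = np.asarray(phase_grid, dtype=float)
    current = calibrate_mean_input(cell, target_rate)
    t_ref, period = _baseline(cell, current, settle, dt)

    def responses(amp: float, phases: np.ndarray) -> np.ndarray:
        out = np.empty(phases.size)
        for k, ph in enumerate(phases):
            spk = single_neuron_spikes(
                cell, current, duration=t_ref + 2.5 * period,
                dt=dt, pulse=(t_ref + ph * period, width, amp),
            )
            nxt = spk[spk > t_ref + 1e-6]
            if nxt.size == 0:
                out[k] = np.nan
                continue
            out[k] = (period - (nxt[0] - t_ref)) / period
        return out

    if amplitude is None:
        probe = np.linspace(0.1, 0.9, 5)
        for amp in (0.25, 0.5, 1.0, 2.0, 4.0):
            if np.nanmax(np.abs(responses(amp, probe))) > 0.005:
                amplitude = amp
                break
        else:
            raise RuntimeError("no ladder amplitude produced a measurable shift")
    resp = responses(amplitude, phase_grid)
    return PRCCurve(phase=phase_grid, response=resp, period=period,
                    amplitude=float(amplitude), width=width)


def sfa_index(spike_times: np.ndarray) -> float | None:
    """Adaptation index of an induced burst.

    ``(ISI_last - ISI_first)/(ISI_last + ISI_first)``: bounded in (-1, 1),
    0 for a perfectly regular train, positive when intervals lengthen.
    None (undefined marker) with fewer than 4 spikes.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 4:
        return None
    isi = np.diff(t)
    first, last = isi[0], isi[-1]
    if first + last == 0:
        return 0.0
    return float((last - first) / (last + first))


def sfa_burst(
    cell: CellParams,
    current: float,
    duration: float = 2000.0,
    dt: float = 0.05,
) -> np.ndarray:
    """Spike times of the burst induced by a current step from rest."""
    return single_neuron_spikes(cell, current, duration=duration, dt=dt)


@dataclass
class SFAIndexGrid:
    """Adaptation index across the (g_ks, current) plane.

    nan marks cells with fewer than 4 spikes (index undefined there, as the
    first and last two inter-spike intervals are required).
    """

    g_ks: np.ndarray
    current: np.ndarray
    index: np.ndarray   # (len(g_ks), len(current)), nan where undefined
    n_spikes: np.ndarray


def sfa_grid(
    base_cell: CellParams,
    g_ks_values: np.ndarray,
    currents: np.ndarray,
    duration: float = 2000.0,
    dt: float = 0.05,
) -> SFAIndexGrid:
    g_ks_values = np.asarray(g_ks_values, dtype=float)
    currents = np.asarray(currents, dtype=float)
    idx = np.full((g_ks_values.size, currents.size), np.nan)
    cnt = np.zeros_like(idx, dtype=int)
    for a, g in enumerate(g_ks_values):
        cell = base_cell.with_gks(g)
        for b, cur in enumerate(currents):
            spk = sfa_burst(cell, cur, duration, dt)
            cnt[a, b] = spk.size
            val = sfa_index(spk)
            if val is not None:
                idx[a, b] = val
    return SFAIndexGrid(g_ks=g_ks_values, current=currents, index=idx,
                        n_spikes=cnt)
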