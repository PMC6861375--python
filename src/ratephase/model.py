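"""Ionic dynamics of the Ks neuron and the double-exponential synapse.

Pure functions of state — no integration logic lives here.  The network
integrator (:mod:`ratephase.simulator`) carries a jit-compiled copy of the
same arithmetic for speed; the functions in this module are the readable
reference and are cross-checked against the integrator in the test suite.

Membrane equation::

    c_m dV/dt = I_syn + I_ext
                - g_na m_inf(V)^3 h (V - e_na)
                - g_kdr n^4 (V - e_k)
                - g_ks s (V - e_k)
                - g_l (V - e_l)

with instantaneous sodium activation (``m_inf^3`` appears directly in the
ODE) and first-order gates ``dx/dt = (x_inf(V) - x)/tau_x(V)`` for x = h, n,
s.  The slow gate s has a voltage-independent time constant of 75 ms; its
conductance ``g_ks`` is the acetylcholine proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CellParams, SynapseParams

__all__ = [
    "NeuronState",
    "synaptic_pulse",
    "synaptic_current",
    "membrane_derivative",
]


@dataclass
class NeuronState:
    """Per-neuron dynamical state.

    ``v`` in mV; ``h``, ``n``, ``s`` dimensionless in [0, 1];
    ``t_last_spike`` (ms) is the most recent spike time per neuron and
    drives the synaptic pulse (-inf if the neuron never fired).
    """

    v: np.ndarray
    h: np.ndarray
    n: np.ndarray
    s: np.ndarray
    t_last_spike: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.atleast_1d(np.asarray(self.v, dtype=float))
        for name in ("h", "n", "s"):
            x = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any((x < 0) | (x > 1)):
                raise ValueError(f"gating variable {name} outside [0, 1]")
            setattr(self, name, x)
        self.t_last_spike = np.atleast_1d(
            np.asarray(self.t_last_spike, dtype=float)
        )

    @classmethod
    def resting(cls, cell: CellParams, v0: float | np.ndarray = -65.0) -> "NeuronState":
        """State with gates at their steady values for voltage ``v0``."""
        v = np.atleast_1d(np.asarray(v0, dtype=float))
        g = cell.gating
        return cls(
            v=v, h=g.h_inf(v), n=g.n_inf(v), s=g.s_inf(v),
            t_last_spike=np.full(v.shape, -np.inf),
        )


def synaptic_pulse(t, t_spike, syn: SynapseParams):
    """Normalised conductance transient driven by the last presynaptic spike.

    ``g(t) = max(B [exp(-(dt-tau_d)/tau_s) - exp(-(dt-tau_d)/tau_f)], 0)``
    with ``dt = t - t_spike`` and ``B`` the normalisation that makes the
    peak exactly 1 at ``dt = syn.t_peak``.  Zero before the delay
    (the max(., 0) clip) and for ``t_spike = -inf``.  Broadcasts over
    array arguments; dimensionless result in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    t_spike = np.asarray(t_spike, dtype=float)
    ts, tf, td = syn.tau_s, syn.tau_f, syn.tau_d
    dt_peak = syn.t_peak - td  # time from delay end to peak
    norm = np.exp(-dt_peak / ts) - np.exp(-dt_peak / tf)
    with np.errstate(over="ignore", invalid="ignore"):
        lag = t - t_spike - td
        raw = (np.exp(-lag / ts) - np.exp(-lag / tf)) / norm
        raw = np.where(np.isfinite(lag), raw, 0.0)
    return np.maximum(raw, 0.0)


def synaptic_current(
    v_i: float,
    pulses: np.ndarray,
    adjacency_row: np.ndarray,
    ei_labels: np.ndarray,
    syn: SynapseParams,
) -> float:
    """Total synaptic drive onto one neuron (uA/cm^2).

    ``I = w_e sum_j A_ij g_j (e_e - V_i) + w_i sum_j A_ij g_j (e_i - V_i)``
    where the first sum runs over excitatory presynaptic neurons and the
    second over inhibitory ones.  ``ei_labels`` is True for excitatory.
    """
    pulses = np.asarray(pulses, dtype=float)
    adjacency_row = np.asarray(adjacency_row)
    ei_labels = np.asarray(ei_labels, dtype=bool)
    if not (pulses.shape == adjacency_row.shape == ei_labels.shape):
        raise ValueError("pulses, adjacency_row and ei_labels must have equal length")
    gated = adjacency_row * pulses
    g_e = float(np.sum(gated[ei_labels]))
    g_i = float(np.sum(gated[~ei_labels]))
    return syn.w_e * g_e * (syn.e_e - v_i) + syn.w_i * g_i * (syn.e_i - v_i)


def membrane_derivative(
    state: NeuronState,
    i_syn,
    i_ext,
    cell: CellParams,
) -> NeuronState:
    """Time derivative of (V, h, n, s); currents in uA/cm^2.

    Returns a :class:`NeuronState` whose fields hold the derivatives (the
    ``t_last_spike`` slot is zero — it is not a differential variable).
    """
    g = cell.gating
    v, h, n, s = state.v, state.h, state.n, state.s
    m3 = g.m_inf(v) ** 3
    i_ion = (
        cell.g_na * m3 * h * (v - cell.e_na)
        + cell.g_kdr * n**4 * (v - cell.e_k)
        + cell.g_ks * s * (v - cell.e_k)
        + cell.g_l * (v - cell.e_l)
    )
    dv = (np.asarray(i_syn, dtype=float) + np.asarray(i_ext, dtype=float) - i_ion) / cell.c_m
    dh = (g.h_inf(v) - h) / g.tau_h(v)
    dn = (g.n_inf(v) - n) / g.tau_n(v)
    ds = (g.s_inf(v) - s) / cell.tau_s
    out = NeuronState.__new__(NeuronState)
    out.v, out.h, out.n, out.s = dv, dh, dn, ds
    out.t_last_spike = np.zeros_like(dv)
    return out
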