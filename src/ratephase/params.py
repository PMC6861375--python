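"""Parameter containers for the Ks neuron and its synapses.

The single-compartment Ks model has fast sodium, delayed-rectifier potassium,
leak and a slow non-inactivating potassium (M-type) current.  The maximal
slow-potassium conductance ``g_ks`` is the control parameter of the whole
package: it is swept between 0 and 1.5 mS/cm^2 and stands in (inversely) for
acetylcholine concentration, since muscarinic receptor activation shuts the
M-current down.

Units are mV / ms / uA/cm^2 / mS/cm^2 / uF/cm^2 throughout the package.

The numeric values live in a versioned YAML file (``data/ks_model.yaml``);
:func:`load_params` reads and validates it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "GatingSpec",
    "CellParams",
    "SynapseParams",
    "load_params",
    "default_cell",
    "default_synapse",
]

_GKS_MAX = 1.5  # mS/cm^2, upper end of the conductance sweep


@dataclass(frozen=True)
class GatingSpec:
    """Boltzmann steady states and sigmoidal time constants for h, n, s.

    ``x_inf(V) = 1/(1 + exp(sign (V - v_half)/k))`` with sign -1 for the
    activating gates (m, n, s) and +1 for inactivation (h).
    ``tau_x(V) = base + amp/(1 + exp((V - v_half)/k))`` for h and n;
    tau_s is voltage independent.
    """

    m_vhalf: float = -30.0
    m_k: float = 9.5
    h_vhalf: float = -53.0
    h_k: float = 7.0
    h_tau_base: float = 0.37
    h_tau_amp: float = 2.78
    h_tau_vhalf: float = -40.5
    h_tau_k: float = 6.0
    n_vhalf: float = -30.0
    n_k: float = 10.0
    n_tau_base: float = 0.37
    n_tau_amp: float = 1.85
    n_tau_vhalf: float = -27.0
    n_tau_k: float = 15.0
    s_vhalf: float = -39.0
    s_k: float = 5.0

    # steady states -----------------------------------------------------
    def m_inf(self, v):
        import numpy as np

        return 1.0 / (1.0 + np.exp(-(v - self.m_vhalf) / self.m_k))

    def h_inf(self, v):
        import numpy as np

        return 1.0 / (1.0 + np.exp((v - self.h_vhalf) / self.h_k))

    def n_inf(self, v):
        import numpy as np

        return 1.0 / (1.0 + np.exp(-(v - self.n_vhalf) / self.n_k))

    def s_inf(self, v):
        import numpy as np

        return 1.0 / (1.0 + np.exp(-(v - self.s_vhalf) / self.s_k))

    # time constants ----------------------------------------------------
    def tau_h(self, v):
        import numpy as np

        return self.h_tau_base + self.h_tau_amp / (
            1.0 + np.exp((v - self.h_tau_vhalf) / self.h_tau_k)
        )

    def tau_n(self, v):
        import numpy as np

        return self.n_tau_base + self.n_tau_amp / (
            1.0 + np.exp((v - self.n_tau_vhalf) / self.n_tau_k)
        )


@dataclass(frozen=True)
class CellParams:
    """Conductances, reversals, capacitance and gating of the Ks neuron."""

    c_m: float = 1.0
    g_na: float = 24.0
    g_kdr: float = 3.0
    g_ks: float = 0.0
    g_l: float = 0.02
    e_na: float = 55.0
    e_k: float = -90.0
    e_l: float = -60.0
    tau_s: float = 75.0
    gating: GatingSpec = field(default_factory=GatingSpec)

    def __post_init__(self) -> None:
        for name in ("g_na", "g_kdr", "g_ks", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.c_m <= 0:
            raise ValueError("c_m must be positive")
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")

    def with_gks(self, g_ks: float) -> "CellParams":
        """Copy with a different slow-potassium conductance (mS/cm^2)."""
        if not 0.0 <= g_ks <= _GKS_MAX:
            raise ValueError(f"g_ks must lie in [0, {_GKS_MAX}] mS/cm^2, got {g_ks}")
        return replace(self, g_ks=g_ks)


@dataclass(frozen=True)
class SynapseParams:
    """Double-exponential conductance pulse and weights.

    The pulse is normalised to peak at 1 at ``tau_d + t_peak`` after the
    presynaptic spike (see :func:`ratephase.model.synaptic_pulse`); the
    degenerate case tau_s == tau_f is rejected because the normalisation
    constant vanishes.
    """

    tau_d: float = 0.08
    tau_s: float = 3.0
    tau_f: float = 0.3
    w_e: float = 0.02
    w_i: float = 0.02
    e_e: float = 0.0
    e_i: float = -75.0

    def __post_init__(self) -> None:
        if not (self.tau_s > self.tau_f > 0):
            raise ValueError("require tau_s > tau_f > 0")
        if self.tau_d < 0:
            raise ValueError("tau_d must be non-negative")
        if self.w_e < 0 or self.w_i < 0:
            raise ValueError("synaptic weights must be non-negative")

    @property
    def t_peak(self) -> float:
        """Delay-to-peak of the pulse, measured from the presynaptic spike (ms).

        Closed form for the maximum of the normalised double exponential:
        ``t_peak = tau_d + tau_s tau_f ln(tau_s/tau_f) / (tau_s - tau_f)``.
        """
        ts, tf = self.tau_s, self.tau_f
        return self.tau_d + ts * tf * math.log(ts / tf) / (ts - tf)


def _default_path() -> Path:
    return Path(str(resources.files("ratephase").joinpath("data/ks_model.yaml")))


def load_params(path: str | Path | None = None) -> tuple[CellParams, SynapseParams]:
    """Load and validate cell + synapse parameters from a YAML file.

    With no argument the package's versioned default file is used.
    """
    p = Path(path) if path is not None else _default_path()
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    c = raw["cell"]
    g = c["gating"]
    gating = GatingSpec(
        m_vhalf=g["m_inf"]["v_half"], m_k=g["m_inf"]["k"],
        h_vhalf=g["h_inf"]["v_half"], h_k=g["h_inf"]["k"],
        h_tau_base=g["tau_h"]["base"], h_tau_amp=g["tau_h"]["amp"],
        h_tau_vhalf=g["tau_h"]["v_half"], h_tau_k=g["tau_h"]["k"],
        n_vhalf=g["n_inf"]["v_half"], n_k=g["n_inf"]["k"],
        n_tau_base=g["tau_n"]["base"], n_tau_amp=g["tau_n"]["amp"],
        n_tau_vhalf=g["tau_n"]["v_half"], n_tau_k=g["tau_n"]["k"],
        s_vhalf=g["s_inf"]["v_half"], s_k=g["s_inf"]["k"],
    )
    cell = CellParams(
        c_m=c["c_m"], g_na=c["g_na"], g_kdr=c["g_kdr"], g_ks=c["g_ks"],
        g_l=c["g_l"], e_na=c["e_na"], e_k=c["e_k"], e_l=c["e_l"],
        tau_s=c["tau_s"], gating=gating,
    )
    s = raw["synapse"]
    syn = SynapseParams(
        tau_d=s["tau_d"], tau_s=s["tau_s"], tau_f=s["tau_f"],
        w_e=s["w_e"], w_i=s["w_i"], e_e=s["e_e"], e_i=s["e_i"],
    )
    return cell, syn


def default_cell(g_ks: float = 0.0) -> CellParams:
    """The package's default Ks cell at a given slow-K conductance."""
    cell, _ = load_params()
    return cell.with_gks(g_ks)


def default_synapse() -> SynapseParams:
    _, syn = load_params()
    return syn
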