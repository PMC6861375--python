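# Ks neuron model parameters.
#
# Units convention (asserted by the loader, used everywhere in the package):
#   voltage mV, time ms, current density uA/cm^2, conductance mS/cm^2,
#   capacitance uF/cm^2.
#
# The slow potassium conductance g_ks is the control parameter: it is swept
# in [0, 1.5] mS/cm^2 and acts as an inverse proxy for acetylcholine level
# (muscarinic suppression of the M-current).  All other cell constants and
# the gating kinetics are the fixed single-compartment Ks dynamics of
# Stiefel, Gutkin & Sejnowski (2009), as used in subsequent network studies.
cell:
  c_m: 1.0          # uF/cm^2
  g_na: 24.0        # mS/cm^2
  g_kdr: 3.0        # mS/cm^2
  g_ks: 0.0         # mS/cm^2, swept in [0, 1.5]
  g_l: 0.02         # mS/cm^2
  e_na: 55.0        # mV
  e_k: -90.0        # mV
  e_l: -60.0        # mV
  tau_s: 75.0       # ms, voltage independent
  gating:
    # x_inf(V) = 1 / (1 + exp(sign * (V - v_half) / k))
    # sigmoidal tau(V) = base + amp / (1 + exp((V - v_half) / k))
    m_inf:  {v_half: -30.0, k: 9.5}    # activation, instantaneous (m_inf^3 in the ODE)
    h_inf:  {v_half: -53.0, k: 7.0}    # Na inactivation (decreasing sigmoid)
    tau_h:  {base: 0.37, amp: 2.78, v_half: -40.5, k: 6.0}
    n_inf:  {v_half: -30.0, k: 10.0}   # delayed rectifier activation
    tau_n:  {base: 0.37, amp: 1.85, v_half: -27.0, k: 15.0}
    s_inf:  {v_half: -39.0, k: 5.0}    # M-current (slow K) activation
synapse:
  tau_d: 0.08       # ms, synaptic delay
  tau_s: 3.0        # ms, slow decay
  tau_f: 0.3        # ms, fast decay
  w_e: 0.02         # mS/cm^2, excitatory weight
  w_i: 0.02         # mS/cm^2, inhibitory weight
  e_e: 0.0          # mV, excitatory reversal
  e_i: -75.0        # mV, inhibitory reversal
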