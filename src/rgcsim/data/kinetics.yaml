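# Voltage-dependent rate coefficients for every gating particle of the
# seven-conductance RGC membrane.  Each gate carries two rate records
# (alpha = opening, beta = closing), each of the form
#
#   linoid:  r(V) = A * (V - V0) / (1 - exp(-(V - V0) / B))   [limit A*B at V0]
#   exp:     r(V) = A * exp((V - V0) / B)
#   sigmoid: r(V) = A / (1 + exp(-(V - V0) / B))
#
# with V in mV and r in 1/ms.  Na, Ca(L), K and A-type K rates follow the
# classic Fohlmeister-Miller amphibian-RGC equations at their reference
# temperature; the HCN (h) gate and the low-threshold T-type gates are
# standard first-order models expressed in steady-state/time-constant form
# (alpha = x_inf/tau, beta = (1 - x_inf)/tau, written as sigmoid pairs).
#
# Gate usage in the current equations:
#   I_Na  = g_Na  * m^3 h  * (V - E_Na)
#   I_K   = g_K   * n^4    * (V - E_K)
#   I_KA  = g_KA  * a^3 hA * (V - E_K)
#   I_Ca  = g_Ca  * c^3    * (V - E_Ca)      (E_Ca by Nernst)
#   I_T   = g_T   * tm^2 th * (V - E_Ca)
#   I_h   = g_h   * q      * (V - E_h)
#   I_KCa = g_KCa * (Ca/Kd)^2 / (1 + (Ca/Kd)^2) * (V - E_K)   (no V gate)
m:
  alpha: {form: linoid,  A: 0.6,   V0: -30.0, B: 10.0}
  beta:  {form: exp,     A: 20.0,  V0: -55.0, B: -18.0}
h:
  alpha: {form: exp,     A: 0.4,   V0: -50.0, B: -20.0}
  beta:  {form: sigmoid, A: 6.0,   V0: -20.0, B: 10.0}
n:
  alpha: {form: linoid,  A: 0.02,  V0: -40.0, B: 10.0}
  beta:  {form: exp,     A: 0.4,   V0: -50.0, B: -80.0}
a:
  alpha: {form: linoid,  A: 0.006, V0: -90.0, B: 10.0}
  beta:  {form: exp,     A: 0.1,   V0: -30.0, B: -10.0}
hA:
  alpha: {form: exp,     A: 0.04,  V0: -70.0, B: -20.0}
  beta:  {form: sigmoid, A: 0.6,   V0: -40.0, B: 10.0}
c:
  alpha: {form: linoid,  A: 0.3,   V0: -13.0, B: 10.0}
  beta:  {form: exp,     A: 10.0,  V0: -38.0, B: -18.0}
# HCN activation: q_inf = 1/(1 + exp((V + 80)/8)), tau_q = 200 ms
q:
  alpha: {form: sigmoid, A: 0.005, V0: -80.0, B: -8.0}
  beta:  {form: sigmoid, A: 0.005, V0: -80.0, B: 8.0}
# T-type activation: tm_inf = 1/(1 + exp(-(V + 57)/6.2)), tau = 2 ms
tm:
  alpha: {form: sigmoid, A: 0.5,   V0: -57.0, B: 6.2}
  beta:  {form: sigmoid, A: 0.5,   V0: -57.0, B: -6.2}
# T-type inactivation: th_inf = 1/(1 + exp((V + 81)/4)), tau = 30 ms
th:
  alpha: {form: sigmoid, A: 0.03333333333333333, V0: -81.0, B: -4.0}
  beta:  {form: sigmoid, A: 0.03333333333333333, V0: -81.0, B: 4.0}
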