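# Maximum ionic conductances (S/cm^2) for the A2-monostratified and
# D1-bistratified RGC models, per region.
#
# Only base values are listed; the A-type and Ca-activated K conductances are
# derived everywhere as g_KA = 3 * g_K and g_KCa = 0.004 * g_K.
#
# The axon block (AH: axon hillock, SOCB: sodium channel band, NS: narrow
# segment, DA: distal axon) is shared by both cell types; only Na and K
# densities are specified for the axon, the remaining channels are absent
# there (0.0).
A2:
  soma:     {g_Na: 0.35, g_K: 0.12,  g_Ca: 0.137, g_h: 0.0,    g_T: 0.004}
  dendrite: {g_Na: 0.1,  g_K: 0.05,  g_Ca: 0.05,  g_h: 0.0,    g_T: 0.0}
D1:
  soma:     {g_Na: 0.2,  g_K: 0.211, g_Ca: 0.013, g_h: 0.0001, g_T: 0.0024}
  dendrite: {g_Na: 0.08, g_K: 0.08,  g_Ca: 0.01,  g_h: 3.0e-5, g_T: 0.001}
axon:
  AH:   {g_Na: 0.8, g_K: 0.6, g_Ca: 0.0, g_h: 0.0, g_T: 0.0}
  SOCB: {g_Na: 2.4, g_K: 0.8, g_Ca: 0.0, g_h: 0.0, g_T: 0.0}
  NS:   {g_Na: 0.9, g_K: 0.6, g_Ca: 0.0, g_h: 0.0, g_T: 0.0}
  DA:   {g_Na: 0.8, g_K: 0.6, g_Ca: 0.0, g_h: 0.0, g_T: 0.0}
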