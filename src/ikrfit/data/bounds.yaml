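# Default search-space constraints.
#
# Box bounds per parameter plus rate constraints: each transition rate,
# evaluated at the voltage extreme where it is largest (upper voltage for
# the rates that grow with V, lower voltage for those that shrink), must
# lie between k_min and k_max.  In (log prefactor, sensitivity) coordinates
# this carves a band between two parallel lines out of each parameter-pair
# box.  Rates in 1/ms, voltages in mV.

lower:
  p1: 1.0e-7
  p2: 1.0e-7
  p3: 1.0e-7
  p4: 1.0e-7
  p5: 1.0e-7
  p6: 1.0e-7
  p7: 1.0e-7
  p8: 1.0e-7
  p9: 1.0e-5

upper:
  p1: 1.0e+3
  p2: 0.4
  p3: 1.0e+3
  p4: 0.4
  p5: 1.0e+3
  p6: 0.4
  p7: 1.0e+3
  p8: 0.4
  p9: 1.0e+3

rates:
  k_min: 1.67e-5
  k_max: 1.0e+3
  v_lo: -120.0
  v_hi: 60.0
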