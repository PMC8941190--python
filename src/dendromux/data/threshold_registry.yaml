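# Dynamic thresholding function parameters per branch class, on the
# normalized-voltage scale (0 = -70 mV rest, 1 = 40 mV spike peak).
#
# g = a + b*X1 + c*X2 + d*X1*X2 ; f = g if g <= theta else v_max
#
# X1: normalized input summation at the thresholding point.
# X2: number of synapses active on the branch during the run.
#
# theta for the basal rows is not tabulated; it must be supplied or
# estimated from data before the piecewise transform can be applied.
primary:
  a: -0.023
  b: 7.900
  c: 0.007
  d: -0.865
  theta: 0.150
  v_max: 0.975
  r_squared: 0.991
  # With many active synapses the regression plane dips below theta in a
  # region that empirically always spikes; the forced rule covers it.
  forced_spike_rule:
    x2_min: 8
    x1_min: 0.25
secondary:
  a: 0.011
  b: 1.357
  c: 0.004
  d: -0.115
  theta: 0.200
  v_max: 0.830
  r_squared: 0.943
tertiary:
  a: 0.017
  b: 1.395
  c: -0.001
  d: -0.107
  theta: 0.270
  v_max: 0.850
  r_squared: 0.997
basal_a:
  a: -0.0189
  b: 5.9470
  c: 0.0019
  d: -0.4808
  theta: null
  v_max: 0.97
  r_squared: 0.934
basal_b:
  a: -0.0118
  b: 2.6687
  c: 0.0055
  d: -0.2611
  theta: null
  v_max: 0.93
  r_squared: 0.7223
basal_c:
  a: 0.0003
  b: 1.6828
  c: 0.0061
  d: -0.1650
  theta: null
  v_max: 0.87
  r_squared: 0.661
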