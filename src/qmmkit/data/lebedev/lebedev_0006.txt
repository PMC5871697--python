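# Lebedev angular quadrature, 6 points; columns x y z weight (weights sum to 1)
 1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  1.6666666666666671e-01
-1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  1.6666666666666671e-01
 0.0000000000000000e+00  1.0000000000000000e+00  0.0000000000000000e+00  1.6666666666666671e-01
 0.0000000000000000e+00 -1.0000000000000000e+00  0.0000000000000000e+00  1.6666666666666671e-01
 0.0000000000000000e+00  0.0000000000000000e+00  1.0000000000000000e+00  1.6666666666666671e-01
 0.0000000000000000e+00  0.0000000000000000e+00 -1.0000000000000000e+00  1.6666666666666671e-01
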