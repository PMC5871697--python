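# Lebedev angular quadrature, 14 points; columns x y z weight (weights sum to 1)
 1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  6.6666666666666666e-02
-1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  6.6666666666666666e-02
 0.0000000000000000e+00  1.0000000000000000e+00  0.0000000000000000e+00  6.6666666666666666e-02
 0.0000000000000000e+00 -1.0000000000000000e+00  0.0000000000000000e+00  6.6666666666666666e-02
 0.0000000000000000e+00  0.0000000000000000e+00  1.0000000000000000e+00  6.6666666666666666e-02
 0.0000000000000000e+00  0.0000000000000000e+00 -1.0000000000000000e+00  6.6666666666666666e-02
 5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01  7.4999999999999997e-02
-5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01  7.4999999999999997e-02
 5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01  7.4999999999999997e-02
-5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01  7.4999999999999997e-02
 5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01  7.4999999999999997e-02
-5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01  7.4999999999999997e-02
 5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01  7.4999999999999997e-02
-5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01  7.4999999999999997e-02
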