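# Lebedev angular quadrature, 26 points; columns x y z weight (weights sum to 1)
 1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  4.7619047619047623e-02
-1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  4.7619047619047623e-02
 0.0000000000000000e+00  1.0000000000000000e+00  0.0000000000000000e+00  4.7619047619047623e-02
 0.0000000000000000e+00 -1.0000000000000000e+00  0.0000000000000000e+00  4.7619047619047623e-02
 0.0000000000000000e+00  0.0000000000000000e+00  1.0000000000000000e+00  4.7619047619047623e-02
 0.0000000000000000e+00  0.0000000000000000e+00 -1.0000000000000000e+00  4.7619047619047623e-02
 0.0000000000000000e+00  7.0710678118654757e-01  7.0710678118654757e-01  3.8095238095238099e-02
 0.0000000000000000e+00 -7.0710678118654757e-01  7.0710678118654757e-01  3.8095238095238099e-02
 0.0000000000000000e+00  7.0710678118654757e-01 -7.0710678118654757e-01  3.8095238095238099e-02
 0.0000000000000000e+00 -7.0710678118654757e-01 -7.0710678118654757e-01  3.8095238095238099e-02
 7.0710678118654757e-01  0.0000000000000000e+00  7.0710678118654757e-01  3.8095238095238099e-02
-7.0710678118654757e-01  0.0000000000000000e+00  7.0710678118654757e-01  3.8095238095238099e-02
 7.0710678118654757e-01  0.0000000000000000e+00 -7.0710678118654757e-01  3.8095238095238099e-02
-7.0710678118654757e-01  0.0000000000000000e+00 -7.0710678118654757e-01  3.8095238095238099e-02
 7.0710678118654757e-01  7.0710678118654757e-01  0.0000000000000000e+00  3.8095238095238099e-02
-7.0710678118654757e-01  7.0710678118654757e-01  0.0000000000000000e+00  3.8095238095238099e-02
 7.0710678118654757e-01 -7.0710678118654757e-01  0.0000000000000000e+00  3.8095238095238099e-02
-7.0710678118654757e-01 -7.0710678118654757e-01  0.0000000000000000e+00  3.8095238095238099e-02
 5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01  3.2142857142857140e-02
-5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01  3.2142857142857140e-02
 5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01  3.2142857142857140e-02
-5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01  3.2142857142857140e-02
 5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01  3.2142857142857140e-02
-5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01  3.2142857142857140e-02
 5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01  3.2142857142857140e-02
-5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01  3.2142857142857140e-02
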