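# Lebedev angular quadrature, 38 points; columns x y z weight (weights sum to 1)
 1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  9.5238095238095247e-03
-1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  9.5238095238095247e-03
 0.0000000000000000e+00  1.0000000000000000e+00  0.0000000000000000e+00  9.5238095238095247e-03
 0.0000000000000000e+00 -1.0000000000000000e+00  0.0000000000000000e+00  9.5238095238095247e-03
 0.0000000000000000e+00  0.0000000000000000e+00  1.0000000000000000e+00  9.5238095238095247e-03
 0.0000000000000000e+00  0.0000000000000000e+00 -1.0000000000000000e+00  9.5238095238095247e-03
 5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01  3.2142857142857140e-02
-5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01  3.2142857142857140e-02
 5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01  3.2142857142857140e-02
-5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01  3.2142857142857140e-02
 5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01  3.2142857142857140e-02
-5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01  3.2142857142857140e-02
 5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01  3.2142857142857140e-02
-5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01  3.2142857142857140e-02
 4.5970084338098310e-01  8.8807383397711526e-01  0.0000000000000000e+00  2.8571428571428571e-02
-4.5970084338098310e-01  8.8807383397711526e-01  0.0000000000000000e+00  2.8571428571428571e-02
 4.5970084338098310e-01 -8.8807383397711526e-01  0.0000000000000000e+00  2.8571428571428571e-02
-4.5970084338098310e-01 -8.8807383397711526e-01  0.0000000000000000e+00  2.8571428571428571e-02
 8.8807383397711526e-01  4.5970084338098310e-01  0.0000000000000000e+00  2.8571428571428571e-02
-8.8807383397711526e-01  4.5970084338098310e-01  0.0000000000000000e+00  2.8571428571428571e-02
 8.8807383397711526e-01 -4.5970084338098310e-01  0.0000000000000000e+00  2.8571428571428571e-02
-8.8807383397711526e-01 -4.5970084338098310e-01  0.0000000000000000e+00  2.8571428571428571e-02
 4.5970084338098310e-01  0.0000000000000000e+00  8.8807383397711526e-01  2.8571428571428571e-02
-4.5970084338098310e-01  0.0000000000000000e+00  8.8807383397711526e-01  2.8571428571428571e-02
 4.5970084338098310e-01  0.0000000000000000e+00 -8.8807383397711526e-01  2.8571428571428571e-02
-4.5970084338098310e-01  0.0000000000000000e+00 -8.8807383397711526e-01  2.8571428571428571e-02
 8.8807383397711526e-01  0.0000000000000000e+00  4.5970084338098310e-01  2.8571428571428571e-02
-8.8807383397711526e-01  0.0000000000000000e+00  4.5970084338098310e-01  2.8571428571428571e-02
 8.8807383397711526e-01  0.0000000000000000e+00 -4.5970084338098310e-01  2.8571428571428571e-02
-8.8807383397711526e-01  0.0000000000000000e+00 -4.5970084338098310e-01  2.8571428571428571e-02
 0.0000000000000000e+00  4.5970084338098310e-01  8.8807383397711526e-01  2.8571428571428571e-02
 0.0000000000000000e+00 -4.5970084338098310e-01  8.8807383397711526e-01  2.8571428571428571e-02
 0.0000000000000000e+00  4.5970084338098310e-01 -8.8807383397711526e-01  2.8571428571428571e-02
 0.0000000000000000e+00 -4.5970084338098310e-01 -8.8807383397711526e-01  2.8571428571428571e-02
 0.0000000000000000e+00  8.8807383397711526e-01  4.5970084338098310e-01  2.8571428571428571e-02
 0.0000000000000000e+00 -8.8807383397711526e-01  4.5970084338098310e-01  2.8571428571428571e-02
 0.0000000000000000e+00  8.8807383397711526e-01 -4.5970084338098310e-01  2.8571428571428571e-02
 0.0000000000000000e+00 -8.8807383397711526e-01 -4.5970084338098310e-01  2.8571428571428571e-02
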