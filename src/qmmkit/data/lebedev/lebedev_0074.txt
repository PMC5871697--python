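# Lebedev angular quadrature, 74 points; columns x y z weight (weights sum to 1)
 1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  5.1306717973384638e-04
-1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  5.1306717973384638e-04
 0.0000000000000000e+00  1.0000000000000000e+00  0.0000000000000000e+00  5.1306717973384638e-04
 0.0000000000000000e+00 -1.0000000000000000e+00  0.0000000000000000e+00  5.1306717973384638e-04
 0.0000000000000000e+00  0.0000000000000000e+00  1.0000000000000000e+00  5.1306717973384638e-04
 0.0000000000000000e+00  0.0000000000000000e+00 -1.0000000000000000e+00  5.1306717973384638e-04
 0.0000000000000000e+00  7.0710678118654757e-01  7.0710678118654757e-01  1.6604069565742039e-02
 0.0000000000000000e+00 -7.0710678118654757e-01  7.0710678118654757e-01  1.6604069565742039e-02
 0.0000000000000000e+00  7.0710678118654757e-01 -7.0710678118654757e-01  1.6604069565742039e-02
 0.0000000000000000e+00 -7.0710678118654757e-01 -7.0710678118654757e-01  1.6604069565742039e-02
 7.0710678118654757e-01  0.0000000000000000e+00  7.0710678118654757e-01  1.6604069565742039e-02
-7.0710678118654757e-01  0.0000000000000000e+00  7.0710678118654757e-01  1.6604069565742039e-02
 7.0710678118654757e-01  0.0000000000000000e+00 -7.0710678118654757e-01  1.6604069565742039e-02
-7.0710678118654757e-01  0.0000000000000000e+00 -7.0710678118654757e-01  1.6604069565742039e-02
 7.0710678118654757e-01  7.0710678118654757e-01  0.0000000000000000e+00  1.6604069565742039e-02
-7.0710678118654757e-01  7.0710678118654757e-01  0.0000000000000000e+00  1.6604069565742039e-02
 7.0710678118654757e-01 -7.0710678118654757e-01  0.0000000000000000e+00  1.6604069565742039e-02
-7.0710678118654757e-01 -7.0710678118654757e-01  0.0000000000000000e+00  1.6604069565742039e-02
 5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01 -2.9586038961038959e-02
-5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01 -2.9586038961038959e-02
 5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01 -2.9586038961038959e-02
-5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01 -2.9586038961038959e-02
 5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01 -2.9586038961038959e-02
-5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01 -2.9586038961038959e-02
 5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01 -2.9586038961038959e-02
-5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01 -2.9586038961038959e-02
 4.8038446141526142e-01  4.8038446141526142e-01  7.3379938570534275e-01  2.6576207082159461e-02
-4.8038446141526142e-01  4.8038446141526142e-01  7.3379938570534275e-01  2.6576207082159461e-02
 4.8038446141526142e-01 -4.8038446141526142e-01  7.3379938570534275e-01  2.6576207082159461e-02
-4.8038446141526142e-01 -4.8038446141526142e-01  7.3379938570534275e-01  2.6576207082159461e-02
 4.8038446141526142e-01  4.8038446141526142e-01 -7.3379938570534275e-01  2.6576207082159461e-02
-4.8038446141526142e-01  4.8038446141526142e-01 -7.3379938570534275e-01  2.6576207082159461e-02
 4.8038446141526142e-01 -4.8038446141526142e-01 -7.3379938570534275e-01  2.6576207082159461e-02
-4.8038446141526142e-01 -4.8038446141526142e-01 -7.3379938570534275e-01  2.6576207082159461e-02
 4.8038446141526142e-01  7.3379938570534275e-01  4.8038446141526142e-01  2.6576207082159461e-02
-4.8038446141526142e-01  7.3379938570534275e-01  4.8038446141526142e-01  2.6576207082159461e-02
 4.8038446141526142e-01 -7.3379938570534275e-01  4.8038446141526142e-01  2.6576207082159461e-02
-4.8038446141526142e-01 -7.3379938570534275e-01  4.8038446141526142e-01  2.6576207082159461e-02
 4.8038446141526142e-01  7.3379938570534275e-01 -4.8038446141526142e-01  2.6576207082159461e-02
-4.8038446141526142e-01  7.3379938570534275e-01 -4.8038446141526142e-01  2.6576207082159461e-02
 4.8038446141526142e-01 -7.3379938570534275e-01 -4.8038446141526142e-01  2.6576207082159461e-02
-4.8038446141526142e-01 -7.3379938570534275e-01 -4.8038446141526142e-01  2.6576207082159461e-02
 7.3379938570534275e-01  4.8038446141526142e-01  4.8038446141526142e-01  2.6576207082159461e-02
-7.3379938570534275e-01  4.8038446141526142e-01  4.8038446141526142e-01  2.6576207082159461e-02
 7.3379938570534275e-01 -4.8038446141526142e-01  4.8038446141526142e-01  2.6576207082159461e-02
-7.3379938570534275e-01 -4.8038446141526142e-01  4.8038446141526142e-01  2.6576207082159461e-02
 7.3379938570534275e-01  4.8038446141526142e-01 -4.8038446141526142e-01  2.6576207082159461e-02
-7.3379938570534275e-01  4.8038446141526142e-01 -4.8038446141526142e-01  2.6576207082159461e-02
 7.3379938570534275e-01 -4.8038446141526142e-01 -4.8038446141526142e-01  2.6576207082159461e-02
-7.3379938570534275e-01 -4.8038446141526142e-01 -4.8038446141526142e-01  2.6576207082159461e-02
 3.2077264898077640e-01  9.4715622136258792e-01  0.0000000000000000e+00  1.6522170993715710e-02
-3.2077264898077640e-01  9.4715622136258792e-01  0.0000000000000000e+00  1.6522170993715710e-02
 3.2077264898077640e-01 -9.4715622136258792e-01  0.0000000000000000e+00  1.6522170993715710e-02
-3.2077264898077640e-01 -9.4715622136258792e-01  0.0000000000000000e+00  1.6522170993715710e-02
 9.4715622136258792e-01  3.2077264898077640e-01  0.0000000000000000e+00  1.6522170993715710e-02
-9.4715622136258792e-01  3.2077264898077640e-01  0.0000000000000000e+00  1.6522170993715710e-02
 9.4715622136258792e-01 -3.2077264898077640e-01  0.0000000000000000e+00  1.6522170993715710e-02
-9.4715622136258792e-01 -3.2077264898077640e-01  0.0000000000000000e+00  1.6522170993715710e-02
 3.2077264898077640e-01  0.0000000000000000e+00  9.4715622136258792e-01  1.6522170993715710e-02
-3.2077264898077640e-01  0.0000000000000000e+00  9.4715622136258792e-01  1.6522170993715710e-02
 3.2077264898077640e-01  0.0000000000000000e+00 -9.4715622136258792e-01  1.6522170993715710e-02
-3.2077264898077640e-01  0.0000000000000000e+00 -9.4715622136258792e-01  1.6522170993715710e-02
 9.4715622136258792e-01  0.0000000000000000e+00  3.2077264898077640e-01  1.6522170993715710e-02
-9.4715622136258792e-01  0.0000000000000000e+00  3.2077264898077640e-01  1.6522170993715710e-02
 9.4715622136258792e-01  0.0000000000000000e+00 -3.2077264898077640e-01  1.6522170993715710e-02
-9.4715622136258792e-01  0.0000000000000000e+00 -3.2077264898077640e-01  1.6522170993715710e-02
 0.0000000000000000e+00  3.2077264898077640e-01  9.4715622136258792e-01  1.6522170993715710e-02
 0.0000000000000000e+00 -3.2077264898077640e-01  9.4715622136258792e-01  1.6522170993715710e-02
 0.0000000000000000e+00  3.2077264898077640e-01 -9.4715622136258792e-01  1.6522170993715710e-02
 0.0000000000000000e+00 -3.2077264898077640e-01 -9.4715622136258792e-01  1.6522170993715710e-02
 0.0000000000000000e+00  9.4715622136258792e-01  3.2077264898077640e-01  1.6522170993715710e-02
 0.0000000000000000e+00 -9.4715622136258792e-01  3.2077264898077640e-01  1.6522170993715710e-02
 0.0000000000000000e+00  9.4715622136258792e-01 -3.2077264898077640e-01  1.6522170993715710e-02
 0.0000000000000000e+00 -9.4715622136258792e-01 -3.2077264898077640e-01  1.6522170993715710e-02
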