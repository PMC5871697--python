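# Lebedev angular quadrature, 50 points; columns x y z weight (weights sum to 1)
 1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  1.2698412698412700e-02
-1.0000000000000000e+00  0.0000000000000000e+00  0.0000000000000000e+00  1.2698412698412700e-02
 0.0000000000000000e+00  1.0000000000000000e+00  0.0000000000000000e+00  1.2698412698412700e-02
 0.0000000000000000e+00 -1.0000000000000000e+00  0.0000000000000000e+00  1.2698412698412700e-02
 0.0000000000000000e+00  0.0000000000000000e+00  1.0000000000000000e+00  1.2698412698412700e-02
 0.0000000000000000e+00  0.0000000000000000e+00 -1.0000000000000000e+00  1.2698412698412700e-02
 0.0000000000000000e+00  7.0710678118654757e-01  7.0710678118654757e-01  2.2574955908289240e-02
 0.0000000000000000e+00 -7.0710678118654757e-01  7.0710678118654757e-01  2.2574955908289240e-02
 0.0000000000000000e+00  7.0710678118654757e-01 -7.0710678118654757e-01  2.2574955908289240e-02
 0.0000000000000000e+00 -7.0710678118654757e-01 -7.0710678118654757e-01  2.2574955908289240e-02
 7.0710678118654757e-01  0.0000000000000000e+00  7.0710678118654757e-01  2.2574955908289240e-02
-7.0710678118654757e-01  0.0000000000000000e+00  7.0710678118654757e-01  2.2574955908289240e-02
 7.0710678118654757e-01  0.0000000000000000e+00 -7.0710678118654757e-01  2.2574955908289240e-02
-7.0710678118654757e-01  0.0000000000000000e+00 -7.0710678118654757e-01  2.2574955908289240e-02
 7.0710678118654757e-01  7.0710678118654757e-01  0.0000000000000000e+00  2.2574955908289240e-02
-7.0710678118654757e-01  7.0710678118654757e-01  0.0000000000000000e+00  2.2574955908289240e-02
 7.0710678118654757e-01 -7.0710678118654757e-01  0.0000000000000000e+00  2.2574955908289240e-02
-7.0710678118654757e-01 -7.0710678118654757e-01  0.0000000000000000e+00  2.2574955908289240e-02
 5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01  2.1093750000000001e-02
-5.7735026918962573e-01  5.7735026918962573e-01  5.7735026918962573e-01  2.1093750000000001e-02
 5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01  2.1093750000000001e-02
-5.7735026918962573e-01 -5.7735026918962573e-01  5.7735026918962573e-01  2.1093750000000001e-02
 5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01  2.1093750000000001e-02
-5.7735026918962573e-01  5.7735026918962573e-01 -5.7735026918962573e-01  2.1093750000000001e-02
 5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01  2.1093750000000001e-02
-5.7735026918962573e-01 -5.7735026918962573e-01 -5.7735026918962573e-01  2.1093750000000001e-02
 3.0151134457776357e-01  3.0151134457776357e-01  9.0453403373329089e-01  2.0173335537918870e-02
-3.0151134457776357e-01  3.0151134457776357e-01  9.0453403373329089e-01  2.0173335537918870e-02
 3.0151134457776357e-01 -3.0151134457776357e-01  9.0453403373329089e-01  2.0173335537918870e-02
-3.0151134457776357e-01 -3.0151134457776357e-01  9.0453403373329089e-01  2.0173335537918870e-02
 3.0151134457776357e-01  3.0151134457776357e-01 -9.0453403373329089e-01  2.0173335537918870e-02
-3.0151134457776357e-01  3.0151134457776357e-01 -9.0453403373329089e-01  2.0173335537918870e-02
 3.0151134457776357e-01 -3.0151134457776357e-01 -9.0453403373329089e-01  2.0173335537918870e-02
-3.0151134457776357e-01 -3.0151134457776357e-01 -9.0453403373329089e-01  2.0173335537918870e-02
 3.0151134457776357e-01  9.0453403373329089e-01  3.0151134457776357e-01  2.0173335537918870e-02
-3.0151134457776357e-01  9.0453403373329089e-01  3.0151134457776357e-01  2.0173335537918870e-02
 3.0151134457776357e-01 -9.0453403373329089e-01  3.0151134457776357e-01  2.0173335537918870e-02
-3.0151134457776357e-01 -9.0453403373329089e-01  3.0151134457776357e-01  2.0173335537918870e-02
 3.0151134457776357e-01  9.0453403373329089e-01 -3.0151134457776357e-01  2.0173335537918870e-02
-3.0151134457776357e-01  9.0453403373329089e-01 -3.0151134457776357e-01  2.0173335537918870e-02
 3.0151134457776357e-01 -9.0453403373329089e-01 -3.0151134457776357e-01  2.0173335537918870e-02
-3.0151134457776357e-01 -9.0453403373329089e-01 -3.0151134457776357e-01  2.0173335537918870e-02
 9.0453403373329089e-01  3.0151134457776357e-01  3.0151134457776357e-01  2.0173335537918870e-02
-9.0453403373329089e-01  3.0151134457776357e-01  3.0151134457776357e-01  2.0173335537918870e-02
 9.0453403373329089e-01 -3.0151134457776357e-01  3.0151134457776357e-01  2.0173335537918870e-02
-9.0453403373329089e-01 -3.0151134457776357e-01  3.0151134457776357e-01  2.0173335537918870e-02
 9.0453403373329089e-01  3.0151134457776357e-01 -3.0151134457776357e-01  2.0173335537918870e-02
-9.0453403373329089e-01  3.0151134457776357e-01 -3.0151134457776357e-01  2.0173335537918870e-02
 9.0453403373329089e-01 -3.0151134457776357e-01 -3.0151134457776357e-01  2.0173335537918870e-02
-9.0453403373329089e-01 -3.0151134457776357e-01 -3.0151134457776357e-01  2.0173335537918870e-02
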