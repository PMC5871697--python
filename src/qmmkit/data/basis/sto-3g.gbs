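H     0
S    3   1.00
      0.3425250914D+01       0.1543289673D+00
      0.6239137298D+00       0.5353281423D+00
      0.1688554040D+00       0.4446345422D+00
****
He     0
S    3   1.00
      0.6362421394D+01       0.1543289673D+00
      0.1158922999D+01       0.5353281423D+00
      0.3136497915D+00       0.4446345422D+00
****
Li     0
S    3   1.00
      0.1611957475D+02       0.1543289673D+00
      0.2936200663D+01       0.5353281423D+00
      0.7946504870D+00       0.4446345422D+00
SP   3   1.00
      0.6362897469D+00      -0.9996722919D-01       0.1559162750D+00
      0.1478600533D+00       0.3995128261D+00       0.6076837186D+00
      0.4808867840D-01       0.7001154689D+00       0.3919573931D+00
****
C     0
S    3   1.00
      0.7161683735D+02       0.1543289673D+00
      0.1304509632D+02       0.5353281423D+00
      0.3530512160D+01       0.4446345422D+00
SP   3   1.00
      0.2941249355D+01      -0.9996722919D-01       0.1559162750D+00
      0.6834830964D+00       0.3995128261D+00       0.6076837186D+00
      0.2222899159D+00       0.7001154689D+00       0.3919573931D+00
****
N     0
S    3   1.00
      0.9910616896D+02       0.1543289673D+00
      0.1805231239D+02       0.5353281423D+00
      0.4885660238D+01       0.4446345422D+00
SP   3   1.00
      0.3780455879D+01      -0.9996722919D-01       0.1559162750D+00
      0.8784966449D+00       0.3995128261D+00       0.6076837186D+00
      0.2857143744D+00       0.7001154689D+00       0.3919573931D+00
****
O     0
S    3   1.00
      0.1307093214D+03       0.1543289673D+00
      0.2380886605D+02       0.5353281423D+00
      0.6443608313D+01       0.4446345422D+00
SP   3   1.00
      0.5033151319D+01      -0.9996722919D-01       0.1559162750D+00
      0.1169596125D+01       0.3995128261D+00       0.6076837186D+00
      0.3803889600D+00       0.7001154689D+00       0.3919573931D+00
****
Al     0
S    3   1.00
      0.3514214767D+03       0.1543289673D+00
      0.6401186067D+02       0.5353281423D+00
      0.1732410761D+02       0.4446345422D+00
SP   3   1.00
      0.1889939621D+02      -0.9996722919D-01       0.1559162750D+00
      0.4391813233D+01       0.3995128261D+00       0.6076837186D+00
      0.1428353970D+01       0.7001154689D+00       0.3919573931D+00
SP   3   1.00
      0.1395448293D+01      -0.2196203690D+00       0.1058760429D-01
      0.3893265318D+00       0.2255954336D+00       0.5951670053D+00
      0.1523797659D+00       0.9003984260D+00       0.4620010120D+00
****
S     0
S    3   1.00
      0.5331257359D+03       0.1543289673D+00
      0.9710951830D+02       0.5353281423D+00
      0.2628162542D+02       0.4446345422D+00
SP   3   1.00
      0.3332975173D+02      -0.9996722919D-01       0.1559162750D+00
      0.7745117521D+01       0.3995128261D+00       0.6076837186D+00
      0.2518952599D+01       0.7001154689D+00       0.3919573931D+00
SP   3   1.00
      0.2029194274D+01      -0.2196203690D+00       0.1058760429D-01
      0.5661400518D+00       0.2255954336D+00       0.5951670053D+00
      0.2215833792D+00       0.9003984260D+00       0.4620010120D+00
****
Cl     0
S    3   1.00
      0.6013456136D+03       0.1543289673D+00
      0.1095358542D+03       0.5353281423D+00
      0.2964467686D+02       0.4446345422D+00
SP   3   1.00
      0.3896041889D+02      -0.9996722919D-01       0.1559162750D+00
      0.9053563477D+01       0.3995128261D+00       0.6076837186D+00
      0.2944499834D+01       0.7001154689D+00       0.3919573931D+00
SP   3   1.00
      0.2129386495D+01      -0.2196203690D+00       0.1058760429D-01
      0.5940934274D+00       0.2255954336D+00       0.5951670053D+00
      0.2325241410D+00       0.9003984260D+00       0.4620010120D+00
****
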