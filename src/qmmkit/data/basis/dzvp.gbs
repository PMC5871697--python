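H     0
S    4   1.00
     50.9991780              0.0096605
      7.4832181              0.0737289
      1.7774676              0.2958581
      0.5193295              0.7159053
S    1   1.00
      0.1541100              1.0000000
****
He     0
S    5   1.00
    221.3880300              0.0027491
     33.2619660              0.0208658
      7.5616549              0.0970588
      2.0855990              0.2807289
      0.6143392              0.4742218
S    1   1.00
      0.1829212              1.0000000
****
Li     0
S    6   1.00
    605.7053900             -0.0022870
     90.8609070             -0.0174528
     20.6312710             -0.0836970
      5.7384462             -0.2597485
      1.7515261             -0.4794613
      0.5463901             -0.3233006
S    2   1.00
      0.8427233              0.0748609
      0.0674483             -0.6546490
S    1   1.00
      0.0253733              1.0000000
P    1   1.00
      0.0773000              1.0000000
D    1   1.00
      0.1220000              1.0000000
****
C     0
S    6   1.00
   2808.0645000              0.0020178
    421.1382800              0.0154332
     95.5866160              0.0755815
     26.7390040              0.2478282
      8.4328268              0.4793725
      2.7605821              0.3338344
S    2   1.00
      5.4470045             -0.0778408
      0.4792422              0.5689560
S    1   1.00
      0.1461565              1.0000000
P    4   1.00
     18.1308520              0.0158547
      4.0998832              0.0956828
      1.1858370              0.3049119
      0.3685974              0.4935016
P    1   1.00
      0.1097200              1.0000000
D    1   1.00
      0.6000000              1.0000000
****
N     0
S    6   1.00
   3845.4149000              0.0020186
    577.5332300              0.0154078
    131.3198300              0.0753714
     36.8237810              0.2482122
     11.6701150              0.4798274
      3.8542604              0.3318012
S    2   1.00
      7.8295611             -0.0776669
      0.6877351              0.5654598
S    1   1.00
      0.2040388              1.0000000
P    4   1.00
     26.8098410              0.0154663
      6.0681540              0.0964397
      1.7676256              0.3083610
      0.5466727              0.4911597
P    1   1.00
      0.1587289              1.0000000
D    1   1.00
      0.7000000              1.0000000
****
O     0
S    6   1.00
   5222.9022000             -0.0019364
    782.5399400             -0.0148507
    177.2674300             -0.0733187
     49.5166880             -0.2451162
     15.6664400             -0.4802847
      5.1793599             -0.3359427
S    2   1.00
     10.6014410              0.0788058
      0.9423170             -0.5676952
S    1   1.00
      0.2774746              1.0000000
P    4   1.00
     33.4241260              0.0175603
      7.6221714              0.1076300
      2.2382093              0.3235256
      0.6867300              0.4832229
P    1   1.00
      0.1938135              1.0000000
D    1   1.00
      0.8000000              1.0000000
****
Al     0
S    6   1.00
  14724.4510000              0.0018182
   2205.4634000              0.0139581
    499.3020700              0.0695009
    139.5901400              0.2371062
     44.4922770              0.4776104
     14.9056910              0.3476339
S    3   1.00
     30.0750650             -0.0878851
      2.9838328              0.5677371
      1.0209899              0.5105008
S    2   1.00
      1.4927792              0.1341424
      0.1692291             -0.6656758
S    1   1.00
      0.0617449              1.0000000
P    5   1.00
    127.9161300              0.0133024
     29.7767780              0.0896710
      9.0917384              0.2981308
      3.0009865              0.4962628
      0.9695584              0.3301450
P    2   1.00
      0.3756001              0.2050982
      0.1250989              0.5518102
P    1   1.00
      0.0417398              1.0000000
D    1   1.00
      0.3000000              1.0000000
****
S     0
S    6   1.00
  23050.0670000             -0.0017567
   3451.8663000             -0.0134894
    781.2786700             -0.0674325
    218.4765300             -0.2318604
     69.8326320             -0.4749416
     23.4947980             -0.3564992
S    3   1.00
     46.4823770             -0.0940422
      4.8807488              0.5828881
      1.8014758              0.4923262
S    2   1.00
      2.9778039              0.1731553
      0.3942510             -0.6854363
S    1   1.00
      0.1417028              1.0000000
P    5   1.00
    231.3312600              0.0112789
     54.1461640              0.0794257
     16.7576180              0.2808799
      5.7193197              0.5020190
      1.9560351              0.3344146
P    2   1.00
      0.8955912              0.2646811
      0.3094227              0.5496127
P    1   1.00
      0.1021157              1.0000000
D    1   1.00
      0.6500000              1.0000000
****
Cl     0
S    6   1.00
  26351.4580000              0.0017324
   3945.0567000              0.0133109
    892.4383500              0.0666748
    249.4174300              0.2300506
     79.7215720              0.4742307
     26.8311450              0.3595240
S    3   1.00
     52.7853010             -0.0956296
      5.6156429              0.5880840
      2.1059076              0.4866982
S    2   1.00
      3.5586149              0.1806891
      0.4847981             -0.6884829
S    1   1.00
      0.1733310              1.0000000
P    5   1.00
    271.0782100             -0.0109257
     63.5472080             -0.0775909
     19.7371090             -0.2775159
      6.7889937             -0.5031933
      2.3480303             -0.3348426
P    2   1.00
      1.1066864             -0.2765381
      0.3829680             -0.5466768
P    1   1.00
      0.1251133              1.0000000
D    1   1.00
      0.7500000              1.0000000
****
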