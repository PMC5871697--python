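H     0
S    3   1.00
      0.1873113696D+02       0.3349460434D-01
      0.2825394365D+01       0.2347269535D+00
      0.6401216923D+00       0.8137573261D+00
S    1   1.00
      0.1612777588D+00       1.0000000
****
He     0
S    3   1.00
      0.3842163400D+02       0.4013973935D-01
      0.5778030000D+01       0.2612460970D+00
      0.1241774000D+01       0.7931846246D+00
S    1   1.00
      0.2979640000D+00       1.0000000
****
Li     0
S    6   1.00
      0.6424189150D+03       0.2142607810D-02
      0.9679851530D+02       0.1620887150D-01
      0.2209112120D+02       0.7731557250D-01
      0.6201070250D+01       0.2457860520D+00
      0.1935117680D+01       0.4701890040D+00
      0.6367357890D+00       0.3454708450D+00
SP   3   1.00
      0.2324918408D+01      -0.3509174574D-01       0.8941508043D-02
      0.6324303556D+00      -0.1912328431D+00       0.1410094640D+00
      0.7905343475D-01       0.1083987795D+01       0.9453636953D+00
SP   1   1.00
      0.3596197175D-01       0.1000000000D+01       0.1000000000D+01
****
C     0
S    6   1.00
      0.3047524880D+04       0.1834737132D-02
      0.4573695180D+03       0.1403732281D-01
      0.1039486850D+03       0.6884262226D-01
      0.2921015530D+02       0.2321844432D+00
      0.9286662960D+01       0.4679413484D+00
      0.3163926960D+01       0.3623119853D+00
SP   3   1.00
      0.7868272350D+01      -0.1193324198D+00       0.6899906659D-01
      0.1881288540D+01      -0.1608541517D+00       0.3164239610D+00
      0.5442492580D+00       0.1143456438D+01       0.7443082909D+00
SP   1   1.00
      0.1687144782D+00       0.1000000000D+01       0.1000000000D+01
****
N     0
S    6   1.00
      0.4173511460D+04       0.1834772160D-02
      0.6274579110D+03       0.1399462700D-01
      0.1429020930D+03       0.6858655181D-01
      0.4023432930D+02       0.2322408730D+00
      0.1282021290D+02       0.4690699481D+00
      0.4390437010D+01       0.3604551991D+00
SP   3   1.00
      0.1162636186D+02      -0.1149611817D+00       0.6757974388D-01
      0.2716279807D+01      -0.1691174786D+00       0.3239072959D+00
      0.7722183966D+00       0.1145851947D+01       0.7408951398D+00
SP   1   1.00
      0.2120314975D+00       0.1000000000D+01       0.1000000000D+01
****
O     0
S    6   1.00
      0.5484671660D+04       0.1831074430D-02
      0.8252349460D+03       0.1395017220D-01
      0.1880469580D+03       0.6844507810D-01
      0.5296450000D+02       0.2327143360D+00
      0.1689757040D+02       0.4701928980D+00
      0.5799635340D+01       0.3585208530D+00
SP   3   1.00
      0.1553961625D+02      -0.1107775495D+00       0.7087426823D-01
      0.3599933586D+01      -0.1480262627D+00       0.3397528391D+00
      0.1013761750D+01       0.1130767015D+01       0.7271585773D+00
SP   1   1.00
      0.2700058226D+00       0.1000000000D+01       0.1000000000D+01
****
Al     0
S    6   1.00
      0.1398310000D+05       0.1942669947D-02
      0.2098750000D+04       0.1485989959D-01
      0.4777050000D+03       0.7284939800D-01
      0.1343600000D+03       0.2468299932D+00
      0.4287090000D+02       0.4872579866D+00
      0.1451890000D+02       0.3234959911D+00
SP   6   1.00
      0.2396680000D+03      -0.2926190028D-02       0.4602845582D-02
      0.5744190000D+02      -0.3740830036D-01       0.3319896813D-01
      0.1828590000D+02      -0.1144870011D+00       0.1362818692D+00
      0.6599140000D+01       0.1156350011D+00       0.3304756828D+00
      0.2490490000D+01       0.6125950058D+00       0.4491455689D+00
      0.9445450000D+00       0.3937990037D+00       0.2657037450D+00
SP   3   1.00
      0.1277900000D+01      -0.2276069245D+00      -0.1751260189D-01
      0.3975900000D+00       0.1445835873D-02       0.2445330264D+00
      0.1600950000D+00       0.1092794439D+01       0.8049340867D+00
SP   1   1.00
      0.5565770000D-01       0.1000000000D+01       0.1000000000D+01
****
S     0
S    6   1.00
      0.2191710000D+05       0.1869240849D-02
      0.3301490000D+04       0.1423030646D-01
      0.7541460000D+03       0.6969623166D-01
      0.2127110000D+03       0.2384871083D+00
      0.6798960000D+02       0.4833072195D+00
      0.2305150000D+02       0.3380741536D+00
SP   6   1.00
      0.4237350000D+03      -0.2376770499D-02       0.4061009982D-02
      0.1007100000D+03      -0.3169300665D-01       0.3068129986D-01
      0.3215990000D+02      -0.1133170238D+00       0.1304519994D+00
      0.1180790000D+02       0.5609001177D-01       0.3272049985D+00
      0.4631100000D+01       0.5922551243D+00       0.4528509980D+00
      0.1870250000D+01       0.4550060955D+00       0.2560419989D+00
SP   3   1.00
      0.2615840000D+01      -0.2503731142D+00      -0.1451048955D-01
      0.9221670000D+00       0.6695676310D-01       0.3102627765D+00
      0.3412870000D+00       0.1054506269D+01       0.7544824565D+00
SP   1   1.00
      0.1171670000D+00       0.1000000000D+01       0.1000000000D+01
****
Cl     0
S    6   1.00
      0.2518010000D+05       0.1832959848D-02
      0.3780350000D+04       0.1403419883D-01
      0.8604740000D+03       0.6909739426D-01
      0.2421450000D+03       0.2374519803D+00
      0.7733490000D+02       0.4830339599D+00
      0.2624700000D+02       0.3398559718D+00
SP   6   1.00
      0.4917650000D+03      -0.2297391417D-02       0.3989400879D-02
      0.1169840000D+03      -0.3071371894D-01       0.3031770668D-01
      0.3741530000D+02      -0.1125280694D+00       0.1298800286D+00
      0.1378340000D+02       0.4501632776D-01       0.3279510723D+00
      0.5452150000D+01       0.5893533634D+00       0.4535271000D+00
      0.2225880000D+01       0.4652062868D+00       0.2521540556D+00
SP   3   1.00
      0.3186490000D+01      -0.2518280280D+00      -0.1429931472D-01
      0.1144270000D+01       0.6158925141D-01       0.3235723331D+00
      0.4203770000D+00       0.1060184328D+01       0.7435077653D+00
SP   1   1.00
      0.1426570000D+00       0.1000000000D+01       0.1000000000D+01
****
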