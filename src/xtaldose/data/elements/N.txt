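# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 9.81961821e-20 1.10156961e-25 3.97164117e-23
1.09972818e+00 7.31324301e-20 1.32513434e-25 3.64597079e-23
1.20940207e+00 5.44659905e-20 1.59240771e-25 3.34700504e-23
1.33001354e+00 4.05640032e-20 1.91120918e-25 3.07255417e-23
1.46265337e+00 3.02103815e-20 2.29044412e-25 2.82060797e-23
1.60852113e+00 2.24994350e-20 2.74011852e-25 2.58932110e-23
1.76893602e+00 1.67566429e-20 3.27128581e-25 2.37699951e-23
1.94534879e+00 1.24796503e-20 3.89589512e-25 2.18208806e-23
2.13935489e+00 9.29432420e-21 4.62650535e-25 2.00315914e-23
2.35270886e+00 6.92202589e-21 5.47582726e-25 1.83890221e-23
2.58734024e+00 5.15523683e-21 6.45606001e-25 1.68811417e-23
2.84537097e+00 3.83940586e-21 7.57800192e-25 1.54969059e-23
3.12913464e+00 2.85942971e-21 8.84994284e-25 1.42261760e-23
3.44119755e+00 2.12958425e-21 1.02763877e-24 1.30596446e-23
3.78438192e+00 1.58602573e-21 1.18567173e-24 1.19887676e-23
4.16179145e+00 1.18120596e-21 1.35839536e-24 1.10057013e-23
4.57683934e+00 8.79713045e-22 1.54438468e-24 1.01032454e-23
5.03327921e+00 6.55173667e-22 1.74145193e-24 9.27478998e-24
5.53523899e+00 4.87946083e-22 1.94668629e-24 8.51426701e-24
6.08725830e+00 3.63401937e-22 2.15657865e-24 7.81610611e-24
6.69432950e+00 2.70646640e-22 2.36722514e-24 7.17519367e-24
7.36194281e+00 2.01566355e-22 2.57458703e-24 6.58683537e-24
8.09613597e+00 1.50118233e-22 2.77477062e-24 6.04672183e-24
8.90354889e+00 1.11801813e-22 2.96428592e-24 5.55089703e-24
9.79148362e+00 8.32653375e-23 3.14024824e-24 5.09572934e-24
1.07679705e+01 6.16922030e-23 3.30049979e-24 4.43519948e-24
1.18418406e+01 4.56410583e-23 3.44364564e-24 3.80216433e-24
1.30228058e+01 3.37661179e-23 3.56901405e-24 3.25948217e-24
1.43215465e+01 2.49808125e-23 3.67656127e-24 2.79425692e-24
1.57498083e+01 1.84812774e-23 3.76674470e-24 2.39543319e-24
1.73205081e+01 1.36727985e-23 3.84038665e-24 2.05353348e-24
1.90478508e+01 1.01153949e-23 3.89854541e-24 1.76043305e-24
2.09474584e+01 7.48356040e-24 3.94240451e-24 1.50916679e-24
2.30365103e+01 5.53647949e-24 3.97318486e-24 1.29376371e-24
2.53338996e+01 4.09599221e-24 3.99208047e-24 1.10910507e-24
2.78604033e+01 3.03029249e-24 4.00021540e-24 9.50802727e-25
3.06388706e+01 2.24754376e-24 3.99861857e-24 8.09446502e-25
3.36944295e+01 1.68185219e-24 3.98821232e-24 6.72483619e-25
3.70547136e+01 1.25854137e-24 3.96981112e-24 5.58695623e-25
4.07501128e+01 9.41775015e-25 3.94412716e-24 4.64161193e-25
4.48140475e+01 7.04736612e-25 3.91178040e-24 3.85622519e-25
4.92832709e+01 5.27359172e-25 3.87331103e-24 3.20373028e-25
5.41982019e+01 3.94626434e-25 3.82919301e-24 2.66164117e-25
5.96032900e+01 2.95301629e-25 3.77984754e-24 2.21127657e-25
6.55474177e+01 2.20976206e-25 3.72565598e-24 1.83711619e-25
7.20843424e+01 1.65357989e-25 3.66697148e-24 1.52626584e-25
7.92731828e+01 1.23738501e-25 3.60412926e-24 1.26801311e-25
8.71789531e+01 9.25943572e-26 3.53745507e-24 1.05345819e-25
9.58731516e+01 6.92889836e-26 3.46727196e-24 8.75207158e-26
1.05434407e+02 5.26791268e-26 3.39390506e-24 7.27117204e-26
1.15949188e+02 4.05605507e-26 3.31768460e-24 6.04084899e-26
1.27512590e+02 3.12297940e-26 3.23894709e-24 5.01870350e-26
1.40229188e+02 2.40455323e-26 3.15803481e-24 4.16951075e-26
1.54213990e+02 1.85139749e-26 3.07529388e-24 3.46400617e-26
1.69593471e+02 1.42549253e-26 2.99107106e-24 2.87787692e-26
1.86506720e+02 1.09756493e-26 2.90570974e-24 2.39092402e-26
2.05106696e+02 8.45075475e-27 2.81954528e-24 1.98636628e-26
2.25561613e+02 6.50669986e-27 2.73290029e-24 1.65026198e-26
2.48056463e+02 5.00986531e-27 2.64607996e-24 1.37102841e-26
2.72794682e+02 3.85737024e-27 2.55936807e-24 1.13904272e-26
3.00000000e+02 2.97000104e-27 2.47302370e-24 9.46310310e-27
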