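# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 1.83806001e-18 7.00000712e-26 1.63234452e-21
1.09972818e+00 1.40851247e-18 8.45609088e-26 1.49849400e-21
1.20940207e+00 1.07934853e-18 1.02130421e-25 1.37561907e-21
1.33001354e+00 8.27108932e-19 1.23321555e-25 1.26281976e-21
1.46265337e+00 6.33816760e-19 1.48868304e-25 1.15926988e-21
1.60852113e+00 4.85696224e-19 1.79647913e-25 1.06421097e-21
1.76893602e+00 3.72190887e-19 2.16706399e-25 9.76946797e-22
1.94534879e+00 2.85211310e-19 2.61287509e-25 8.96838192e-22
2.13935489e+00 2.18558525e-19 3.14865067e-25 8.23298408e-22
2.35270886e+00 1.67482240e-19 3.79178316e-25 7.55788809e-22
2.58734024e+00 1.28342285e-19 4.56269423e-25 6.93814925e-22
2.84537097e+00 9.83491874e-20 5.48521564e-25 6.36922835e-22
3.12913464e+00 7.53653610e-20 6.58695049e-25 5.84695835e-22
3.44119755e+00 5.77527664e-20 7.89957585e-25 5.36751395e-22
3.78438192e+00 4.42561673e-20 9.45903057e-25 4.92738348e-22
4.16179145e+00 3.39136714e-20 1.13055106e-24 4.52334324e-22
4.57683934e+00 2.59881770e-20 1.34831703e-24 4.15243387e-22
5.03327921e+00 1.99148401e-20 1.60394040e-24 3.81193868e-22
5.53523899e+00 1.52608187e-20 1.90235626e-24 3.49936374e-22
6.08725830e+00 1.16944241e-20 2.24849562e-24 3.21241961e-22
6.69432950e+00 8.96148225e-21 2.64700119e-24 2.94900460e-22
7.36194281e+00 6.86721836e-21 3.10185225e-24 2.70718934e-22
8.09613597e+00 5.26237588e-21 3.61590339e-24 2.48520267e-22
8.90354889e+00 4.03257890e-21 4.19036048e-24 2.28141868e-22
8.97810210e+00 3.93951696e-21 4.24361767e-24 2.26436139e-22
8.97900000e+00 3.07196292e-20 4.24425917e-24 2.26415759e-22
9.79148362e+00 2.34850952e-20 4.82423995e-24 2.09434476e-22
1.07679705e+01 1.74003649e-20 5.51388260e-24 1.82286699e-22
1.18418406e+01 1.28731190e-20 6.25261212e-24 1.56268954e-22
1.30228058e+01 9.52377685e-21 7.03063363e-24 1.33964717e-22
1.43215465e+01 7.04587020e-21 7.83524892e-24 1.14843960e-22
1.57498083e+01 5.21266800e-21 8.65142107e-24 9.84523039e-23
1.73205081e+01 3.85643035e-21 9.46265585e-24 8.44002261e-23
1.90478508e+01 2.85306009e-21 1.02520988e-23 7.23537985e-23
2.09474584e+01 2.11074780e-21 1.10036944e-23 6.20267551e-23
2.30365103e+01 1.56157114e-21 1.17032379e-23 5.31736886e-23
2.53338996e+01 1.15527985e-21 1.23391753e-23 4.55842186e-23
2.78604033e+01 8.54697881e-22 1.29030645e-23 3.90779921e-23
3.06388706e+01 6.33922599e-22 1.33896832e-23 3.32682512e-23
3.36944295e+01 4.74368567e-22 1.37968304e-23 2.76390767e-23
3.70547136e+01 3.54973206e-22 1.41249098e-23 2.29623901e-23
4.07501128e+01 2.65628850e-22 1.43763941e-23 1.90770250e-23
4.48140475e+01 1.98771865e-22 1.45552624e-23 1.58490855e-23
4.92832709e+01 1.48742331e-22 1.46664755e-23 1.31673315e-23
5.41982019e+01 1.11304892e-22 1.47155323e-23 1.09393452e-23
5.96032900e+01 8.32902031e-23 1.47081228e-23 9.08834672e-24
6.55474177e+01 6.23266222e-23 1.46498784e-23 7.55054753e-24
7.20843424e+01 4.66394328e-23 1.45462066e-23 6.27295259e-24
7.92731828e+01 3.49006029e-23 1.44021962e-23 5.21153387e-24
8.71789531e+01 2.61163572e-23 1.42225729e-23 4.32971314e-24
9.58731516e+01 1.95430467e-23 1.40116916e-23 3.59710142e-24
1.05434407e+02 1.48582153e-23 1.37735505e-23 2.98845171e-24
1.15949188e+02 1.14401553e-23 1.35118173e-23 2.48278894e-24
1.27512590e+02 8.80840343e-24 1.32298589e-23 2.06268714e-24
1.40229188e+02 6.78207320e-24 1.29307719e-23 1.71366892e-24
1.54213990e+02 5.22189036e-24 1.26174069e-23 1.42370654e-24
1.69593471e+02 4.02061996e-24 1.22923895e-23 1.18280741e-24
1.86506720e+02 3.09569596e-24 1.19581346e-23 9.82669773e-25
2.05106696e+02 2.38354621e-24 1.16168557e-23 8.16396542e-25
2.25561613e+02 1.83522304e-24 1.12705712e-23 6.78257674e-25
2.48056463e+02 1.41303893e-24 1.09211075e-23 5.63492675e-25
2.72794682e+02 1.08797622e-24 1.05701019e-23 4.68146558e-25
3.00000000e+02 8.37692602e-25 1.02190060e-23 3.88933537e-25
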