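# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 1.33809909e-18 7.25535762e-26 1.22882578e-21
1.09972818e+00 1.02539049e-18 8.76351481e-26 1.12806336e-21
1.20940207e+00 7.85760679e-19 1.05828208e-25 1.03556336e-21
1.33001354e+00 6.02131434e-19 1.27764458e-25 9.50648259e-22
1.46265337e+00 4.61415637e-19 1.54199345e-25 8.72696107e-22
1.60852113e+00 3.53584579e-19 1.86034302e-25 8.01135948e-22
1.76893602e+00 2.70953225e-19 2.24342084e-25 7.35443647e-22
1.94534879e+00 2.07632500e-19 2.70395189e-25 6.75138045e-22
2.13935489e+00 1.59109584e-19 3.25697128e-25 6.19777439e-22
2.35270886e+00 1.21926287e-19 3.92015892e-25 5.68956344e-22
2.58734024e+00 9.34325833e-20 4.71418391e-25 5.22302525e-22
2.84537097e+00 7.15977484e-20 5.66303833e-25 4.79474270e-22
3.12913464e+00 5.48656303e-20 6.79432859e-25 4.40157887e-22
3.44119755e+00 4.20437438e-20 8.13947809e-25 4.04065405e-22
3.78438192e+00 3.22182828e-20 9.73377628e-25 3.70932469e-22
4.16179145e+00 2.46889942e-20 1.16161883e-24 3.40516398e-22
4.57683934e+00 1.89192713e-20 1.38288171e-24 3.12594414e-22
5.03327921e+00 1.44979105e-20 1.64158912e-24 2.86962002e-22
5.53523899e+00 1.11098046e-20 1.94221417e-24 2.63431421e-22
6.08725830e+00 8.51348607e-21 2.28904471e-24 2.41830323e-22
6.69432950e+00 6.52391716e-21 2.68586632e-24 2.22000492e-22
7.11128880e+00 5.50849538e-21 2.96544332e-24 2.10250399e-22
7.11200000e+00 4.51570158e-20 2.96592407e-24 2.10231477e-22
7.36194281e+00 4.05716893e-20 3.13556573e-24 2.03796686e-22
8.09613597e+00 3.02161058e-20 3.63967059e-24 1.87085574e-22
8.90354889e+00 2.25036982e-20 4.19786182e-24 1.71744754e-22
9.79148362e+00 1.67598179e-20 4.80751724e-24 1.57661866e-22
1.07679705e+01 1.24175332e-20 5.46336411e-24 1.37225072e-22
1.18418406e+01 9.18672583e-21 6.15732673e-24 1.17638964e-22
1.30228058e+01 6.79651348e-21 6.87864442e-24 1.00848378e-22
1.43215465e+01 5.02818918e-21 7.61430060e-24 8.64543092e-23
1.57498083e+01 3.71994944e-21 8.34974946e-24 7.41147028e-23
1.73205081e+01 2.75208893e-21 9.06986333e-24 6.35363259e-23
1.90478508e+01 2.03604743e-21 9.75997245e-24 5.44677987e-23
2.09474584e+01 1.50630639e-21 1.04068448e-23 4.66936205e-23
2.30365103e+01 1.11439395e-21 1.09994679e-23 4.00290493e-23
2.53338996e+01 8.24449714e-22 1.15295403e-23 3.43157110e-23
2.78604033e+01 6.09943488e-22 1.19916434e-23 2.94178364e-23
3.06388706e+01 4.52390218e-22 1.23831251e-23 2.50442748e-23
3.36944295e+01 3.38526659e-22 1.27037656e-23 2.08066432e-23
3.70547136e+01 2.53321788e-22 1.29553160e-23 1.72860426e-23
4.07501128e+01 1.89562407e-22 1.31409935e-23 1.43611473e-23
4.48140475e+01 1.41850831e-22 1.32649986e-23 1.19311607e-23
4.92832709e+01 1.06147936e-22 1.33320984e-23 9.91234150e-24
5.41982019e+01 7.94312182e-23 1.33472939e-23 8.23511778e-24
5.96032900e+01 5.94389177e-23 1.33155763e-23 6.84168972e-24
6.55474177e+01 4.44785440e-23 1.32417624e-23 5.68403749e-24
7.20843424e+01 3.32835952e-23 1.31303967e-23 4.72226650e-24
7.92731828e+01 2.49063394e-23 1.29857040e-23 3.92323255e-24
8.71789531e+01 1.86375822e-23 1.28115770e-23 3.25939962e-24
9.58731516e+01 1.39466287e-23 1.26115882e-23 2.70789095e-24
1.05434407e+02 1.06033627e-23 1.23890133e-23 2.24970063e-24
1.15949188e+02 8.16411086e-24 1.21468609e-23 1.86903868e-24
1.27512590e+02 6.28599699e-24 1.18879019e-23 1.55278686e-24
1.40229188e+02 4.83993406e-24 1.16146962e-23 1.29004663e-24
1.54213990e+02 3.72653085e-24 1.13296133e-23 1.07176351e-24
1.69593471e+02 2.86926061e-24 1.10348483e-23 8.90415119e-25
1.86506720e+02 2.20920121e-24 1.07324320e-23 7.39751893e-25
2.05106696e+02 1.70098525e-24 1.04242363e-23 6.14581728e-25
2.25561613e+02 1.30968190e-24 1.01119767e-23 5.10591056e-25
2.48056463e+02 1.00839597e-24 9.79721267e-24 4.24196189e-25
2.72794682e+02 7.76419395e-25 9.48134781e-24 3.52419817e-25
3.00000000e+02 5.97807902e-25 9.16563039e-24 2.92788410e-25
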