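# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 2.92070696e-19 1.01994547e-25 7.78441670e-23
1.09972818e+00 2.17522100e-19 1.22864591e-25 7.14610276e-23
1.20940207e+00 1.62001408e-19 1.47891133e-25 6.56012988e-23
1.33001354e+00 1.20651907e-19 1.77851815e-25 6.02220617e-23
1.46265337e+00 8.98565194e-20 2.13647817e-25 5.52839163e-23
1.60852113e+00 6.69213963e-20 2.56313845e-25 5.07506935e-23
1.76893602e+00 4.98402711e-20 3.07024342e-25 4.65891903e-23
1.94534879e+00 3.71189598e-20 3.67093402e-25 4.27689259e-23
2.13935489e+00 2.76446566e-20 4.37965032e-25 3.92619192e-23
2.35270886e+00 2.05885898e-20 5.21189698e-25 3.60424833e-23
2.58734024e+00 1.53335249e-20 6.18382430e-25 3.30870378e-23
2.84537097e+00 1.14197713e-20 7.31157730e-25 3.03739357e-23
3.12913464e+00 8.50497041e-21 8.61037241e-25 2.78833050e-23
3.44119755e+00 6.33414803e-21 1.00932834e-24 2.55969035e-23
3.78438192e+00 4.71740986e-21 1.17697572e-24 2.34979845e-23
4.16179145e+00 3.51333055e-21 1.36439408e-24 2.15711746e-23
4.57683934e+00 2.61658239e-21 1.57129734e-24 1.98023610e-23
5.03327921e+00 1.94872168e-21 1.79654786e-24 1.81785884e-23
5.53523899e+00 1.45132681e-21 2.03805441e-24 1.66879633e-23
6.08725830e+00 1.08088781e-21 2.29274894e-24 1.53195680e-23
6.69432950e+00 8.05000262e-22 2.55666436e-24 1.40633796e-23
7.36194281e+00 5.99530695e-22 2.82512185e-24 1.29101973e-23
8.09613597e+00 4.46505513e-22 3.09301418e-24 1.18515748e-23
8.90354889e+00 3.32538725e-22 3.35515100e-24 1.08797582e-23
9.79148362e+00 2.47661004e-22 3.60661689e-24 9.98762951e-24
1.07679705e+01 1.83494758e-22 3.84308961e-24 8.69299098e-24
1.18418406e+01 1.35752891e-22 4.06107569e-24 7.45224209e-24
1.30228058e+01 1.00432556e-22 4.25803929e-24 6.38858505e-24
1.43215465e+01 7.43019039e-23 4.43242248e-24 5.47674357e-24
1.57498083e+01 5.49699534e-23 4.58357371e-24 4.69504904e-24
1.73205081e+01 4.06678110e-23 4.71161244e-24 4.02492562e-24
1.90478508e+01 3.00868155e-23 4.81726066e-24 3.45044878e-24
2.09474584e+01 2.22587950e-23 4.90166842e-24 2.95796691e-24
2.30365103e+01 1.64674774e-23 4.96625328e-24 2.53577688e-24
2.53338996e+01 1.21829512e-23 5.01256521e-24 2.17384595e-24
2.78604033e+01 9.01317766e-24 5.04218183e-24 1.86357334e-24
3.06388706e+01 6.68500195e-24 5.05663347e-24 1.58651514e-24
3.36944295e+01 5.00243216e-24 5.05735472e-24 1.31806789e-24
3.70547136e+01 3.74335381e-24 5.04565752e-24 1.09504342e-24
4.07501128e+01 2.80117697e-24 5.02272078e-24 9.09755939e-25
4.48140475e+01 2.09613967e-24 4.98959174e-24 7.55820137e-25
4.92832709e+01 1.56855549e-24 4.94719534e-24 6.27931136e-25
5.41982019e+01 1.17376068e-24 4.89634820e-24 5.21681670e-25
5.96032900e+01 8.78333051e-25 4.83777506e-24 4.33410208e-25
6.55474177e+01 6.57262561e-25 4.77212590e-24 3.60074773e-25
7.20843424e+01 4.91834019e-25 4.69999249e-24 2.99148104e-25
7.92731828e+01 3.68042722e-25 4.62192345e-24 2.48530569e-25
8.71789531e+01 2.75408857e-25 4.53843745e-24 2.06477804e-25
9.58731516e+01 2.06090310e-25 4.45003401e-24 1.71540603e-25
1.05434407e+02 1.56686634e-25 4.35720187e-24 1.42514972e-25
1.15949188e+02 1.20641638e-25 4.26042466e-24 1.18400640e-25
1.27512590e+02 9.28886180e-26 4.16018422e-24 9.83665886e-26
1.40229188e+02 7.15200447e-26 4.05696147e-24 8.17224107e-26
1.54213990e+02 5.50672074e-26 3.95123521e-24 6.78945210e-26
1.69593471e+02 4.23992651e-26 3.84347920e-24 5.64063876e-26
1.86506720e+02 3.26455211e-26 3.73415793e-24 4.68621108e-26
2.05106696e+02 2.51355782e-26 3.62372148e-24 3.89327791e-26
2.25561613e+02 1.93532611e-26 3.51260010e-24 3.23451348e-26
2.48056463e+02 1.49011378e-26 3.40119890e-24 2.68721568e-26
2.72794682e+02 1.14732038e-26 3.28989307e-24 2.23252373e-26
3.00000000e+02 8.83384925e-27 3.17902415e-24 1.85476821e-26
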