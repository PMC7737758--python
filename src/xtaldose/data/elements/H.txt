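# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 1.51071049e-23 1.62814583e-25 6.35462588e-25
1.09972818e+00 1.12511431e-23 1.87200463e-25 5.83355327e-25
1.20940207e+00 8.37938316e-24 2.13659954e-25 5.35520807e-25
1.33001354e+00 6.24061588e-24 2.41931865e-25 4.91608667e-25
1.46265337e+00 4.64775100e-24 2.71647814e-25 4.51297276e-25
1.60852113e+00 3.46145153e-24 3.02345140e-25 4.14291376e-25
1.76893602e+00 2.57794506e-24 3.33491768e-25 3.80319921e-25
1.94534879e+00 1.91994620e-24 3.64520693e-25 3.49134089e-25
2.13935489e+00 1.42989603e-24 3.94869542e-25 3.20505463e-25
2.35270886e+00 1.06492706e-24 4.24019433e-25 2.94224354e-25
2.58734024e+00 7.93113358e-25 4.51527545e-25 2.70098268e-25
2.84537097e+00 5.90677824e-25 4.77049268e-25 2.47950495e-25
3.12913464e+00 4.39912263e-25 5.00348194e-25 2.27618817e-25
3.44119755e+00 3.27628346e-25 5.21294514e-25 2.08954314e-25
3.78438192e+00 2.44003958e-25 5.39854258e-25 1.91820281e-25
4.16179145e+00 1.81723994e-25 5.56072636e-25 1.76091221e-25
4.57683934e+00 1.35340468e-25 5.70054822e-25 1.61651927e-25
5.03327921e+00 1.00795949e-25 5.81946884e-25 1.48396640e-25
5.53523899e+00 7.50686281e-26 5.91918734e-25 1.36228272e-25
6.08725830e+00 5.59079903e-26 6.00150117e-25 1.25057698e-25
6.69432950e+00 4.16379446e-26 6.06819869e-25 1.14803099e-25
7.36194281e+00 3.10102084e-26 6.12098357e-25 1.05389366e-25
8.09613597e+00 2.30951127e-26 6.16142585e-25 9.67475493e-26
8.90354889e+00 1.72002789e-26 6.19093468e-25 8.88143525e-26
9.79148362e+00 1.28100519e-26 6.21074702e-25 8.15316695e-26
1.07679705e+01 9.49110815e-27 6.22192782e-25 7.09631916e-26
1.18418406e+01 7.02170127e-27 6.22537757e-25 6.08346293e-26
1.30228058e+01 5.19478737e-27 6.22184454e-25 5.21517147e-26
1.43215465e+01 3.84320192e-27 6.21193925e-25 4.47081108e-26
1.57498083e+01 2.84327345e-27 6.19615002e-25 3.83269310e-26
1.73205081e+01 2.10350746e-27 6.17485838e-25 3.28565357e-26
1.90478508e+01 1.55621460e-27 6.14835400e-25 2.81669289e-26
2.09474584e+01 1.15131698e-27 6.11684861e-25 2.41466687e-26
2.30365103e+01 8.51766075e-28 6.08048909e-25 2.07002194e-26
2.53338996e+01 6.30152648e-28 6.03936945e-25 1.77456812e-26
2.78604033e+01 4.66198844e-28 5.99354195e-25 1.52128436e-26
3.06388706e+01 3.45775963e-28 5.94302749e-25 1.29511440e-26
3.36944295e+01 2.58746491e-28 5.88782519e-25 1.07597379e-26
3.70547136e+01 1.93621749e-28 5.82792145e-25 8.93912996e-27
4.07501128e+01 1.44888464e-28 5.76329853e-25 7.42657909e-27
4.48140475e+01 1.08421017e-28 5.69394251e-25 6.16996030e-27
4.92832709e+01 8.11321803e-29 5.61985097e-25 5.12596845e-27
5.41982019e+01 6.07117591e-29 5.54103994e-25 4.25862587e-27
5.96032900e+01 4.54310199e-29 5.45755036e-25 3.53804252e-27
6.55474177e+01 3.39963394e-29 5.36945378e-25 2.93938590e-27
7.20843424e+01 2.54396906e-29 5.27685717e-25 2.44202534e-27
7.92731828e+01 1.90366925e-29 5.17990662e-25 2.02882097e-27
8.71789531e+01 1.42452857e-29 5.07878987e-25 1.68553310e-27
9.58731516e+01 1.06598436e-29 4.97373739e-25 1.40033145e-27
1.05434407e+02 8.10448105e-30 4.86502192e-25 1.16338753e-27
1.15949188e+02 6.24008473e-30 4.75295639e-25 9.66535839e-28
1.27512590e+02 4.80458369e-30 4.63789022e-25 8.02992560e-28
1.40229188e+02 3.69931266e-30 4.52020404e-25 6.67121720e-28
1.54213990e+02 2.84830383e-30 4.40030304e-25 5.54240988e-28
1.69593471e+02 2.19306544e-30 4.27860922e-25 4.60460307e-28
1.86506720e+02 1.68856143e-30 4.15555285e-25 3.82547844e-28
2.05106696e+02 1.30011612e-30 4.03156365e-25 3.17818605e-28
2.25561613e+02 1.00103075e-30 3.90706202e-25 2.64041917e-28
2.48056463e+02 7.70748509e-31 3.78245097e-25 2.19364545e-28
2.72794682e+02 5.93441576e-31 3.65810895e-25 1.82246835e-28
3.00000000e+02 4.56923237e-31 3.53438414e-25 1.51409650e-28
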