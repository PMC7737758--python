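# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 2.49305100e-19 8.49730788e-26 3.47915767e-22
1.09972818e+00 1.91043458e-19 1.02554664e-25 3.19387042e-22
1.20940207e+00 1.46397338e-19 1.23726274e-25 2.93197642e-22
1.33001354e+00 1.12184844e-19 1.49199864e-25 2.69155745e-22
1.46265337e+00 8.59676776e-20 1.79819227e-25 2.47085258e-22
1.60852113e+00 6.58773624e-20 2.16580243e-25 2.26824528e-22
1.76893602e+00 5.04820765e-20 2.60652333e-25 2.08225157e-22
1.94534879e+00 3.86846097e-20 3.13400205e-25 1.91150914e-22
2.13935489e+00 2.96441654e-20 3.76404401e-25 1.75476741e-22
2.35270886e+00 2.27164381e-20 4.51478384e-25 1.61087834e-22
2.47175280e+00 1.97841349e-20 4.95891541e-25 1.54088270e-22
2.47200000e+00 2.01741678e-19 4.95985595e-25 1.54074402e-22
2.58734024e+00 1.75145867e-19 5.40678889e-25 1.47878802e-22
2.84537097e+00 1.30441353e-19 6.46305057e-25 1.35752896e-22
3.12913464e+00 9.71472913e-20 7.70880488e-25 1.24621302e-22
3.44119755e+00 7.23512598e-20 9.17111010e-25 1.14402487e-22
3.78438192e+00 5.38842075e-20 1.08780993e-24 1.05021604e-22
4.16179145e+00 4.01307154e-20 1.28578236e-24 9.64099435e-23
4.57683934e+00 2.98876868e-20 1.51366159e-24 8.85044300e-23
5.03327921e+00 2.22591054e-20 1.77369430e-24 8.12471603e-23
5.53523899e+00 1.65776554e-20 2.06747831e-24 7.45849790e-23
6.08725830e+00 1.23463479e-20 2.39566725e-24 6.84690895e-23
6.69432950e+00 9.19504610e-21 2.75766933e-24 6.28546966e-23
7.36194281e+00 6.84808769e-21 3.15138163e-24 5.77006779e-23
8.09613597e+00 5.10017073e-21 3.57301101e-24 5.29692833e-23
8.90354889e+00 3.79839492e-21 4.01703401e-24 4.86258580e-23
9.79148362e+00 2.82888647e-21 4.47633636e-24 4.46385890e-23
1.07679705e+01 2.09595305e-21 4.94254604e-24 3.88523474e-23
1.18418406e+01 1.55062570e-21 5.40653699e-24 3.33069596e-23
1.30228058e+01 1.14718221e-21 5.85904313e-24 2.85530638e-23
1.43215465e+01 8.48707092e-22 6.29129515e-24 2.44776907e-23
1.57498083e+01 6.27889554e-22 6.69558714e-24 2.09839947e-23
1.73205081e+01 4.64524565e-22 7.06569629e-24 1.79889533e-23
1.90478508e+01 3.43664057e-22 7.39711288e-24 1.54213935e-23
2.09474584e+01 2.54249167e-22 7.68707710e-24 1.32203011e-23
2.30365103e+01 1.88098342e-22 7.93445227e-24 1.13333701e-23
2.53338996e+01 1.39158710e-22 8.13948448e-24 9.71576046e-24
2.78604033e+01 1.02952245e-22 8.30350345e-24 8.32903189e-24
3.06388706e+01 7.63588585e-23 8.42861304e-24 7.09075135e-24
3.36944295e+01 5.71398501e-23 8.51740674e-24 5.89095650e-24
3.70547136e+01 4.27581362e-23 8.57272911e-24 4.89417366e-24
4.07501128e+01 3.19962024e-23 8.59749121e-24 4.06605205e-24
4.48140475e+01 2.39429746e-23 8.59453946e-24 3.37805327e-24
4.92832709e+01 1.79166898e-23 8.56657124e-24 2.80646773e-24
5.41982019e+01 1.34071801e-23 8.51608860e-24 2.33159767e-24
5.96032900e+01 1.00326836e-23 8.44538063e-24 1.93707828e-24
6.55474177e+01 7.50752494e-24 8.35652586e-24 1.60931378e-24
7.20843424e+01 5.61793168e-24 8.25140759e-24 1.33700887e-24
7.92731828e+01 4.20393626e-24 8.13173633e-24 1.11077948e-24
8.71789531e+01 3.14583393e-24 7.99907509e-24 9.22829370e-25
9.58731516e+01 2.35404880e-24 7.85486440e-24 7.66681471e-25
1.05434407e+02 1.78973956e-24 7.70044491e-24 6.36954670e-25
1.15949188e+02 1.37801871e-24 7.53707641e-24 5.29178372e-25
1.27512590e+02 1.06101223e-24 7.36595238e-24 4.39638427e-25
1.40229188e+02 8.16931545e-25 7.18821006e-24 3.65249142e-25
1.54213990e+02 6.29000430e-25 7.00493610e-24 3.03446941e-25
1.69593471e+02 4.84301950e-25 6.81716834e-24 2.52102018e-25
1.86506720e+02 3.72890650e-25 6.62589444e-24 2.09444944e-25
2.05106696e+02 2.87108976e-25 6.43204820e-24 1.74005686e-25
2.25561613e+02 2.21060957e-25 6.23650445e-24 1.44562949e-25
2.48056463e+02 1.70206962e-25 6.04007360e-24 1.20102088e-25
2.72794682e+02 1.31051681e-25 5.84349653e-24 9.97801422e-26
3.00000000e+02 1.00903882e-25 5.64744074e-24 8.28967831e-26
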