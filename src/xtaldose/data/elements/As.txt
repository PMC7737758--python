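# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 3.09817137e-18 6.70878076e-26 2.28369367e-21
1.09972818e+00 2.37414066e-18 8.10526069e-26 2.09643321e-21
1.20940207e+00 1.81931313e-18 9.79074042e-26 1.92452790e-21
1.33001354e+00 1.39414666e-18 1.18243027e-25 1.76671865e-21
1.46265337e+00 1.06833995e-18 1.42767925e-25 1.62184958e-21
1.60852113e+00 8.18673019e-19 1.72330196e-25 1.48885963e-21
1.76893602e+00 6.27352287e-19 2.07943092e-25 1.36677472e-21
1.94534879e+00 4.80742474e-19 2.50814299e-25 1.25470063e-21
2.13935489e+00 3.68394809e-19 3.02379093e-25 1.15181651e-21
2.35270886e+00 2.82302361e-19 3.64337272e-25 1.05736877e-21
2.58734024e+00 2.16329386e-19 4.38693394e-25 9.70665649e-22
2.84537097e+00 1.65774042e-19 5.27799254e-25 8.91072092e-22
3.12913464e+00 1.27033287e-19 6.34396719e-25 8.18005122e-22
3.44119755e+00 9.73460968e-20 7.61657893e-25 7.50929567e-22
3.78438192e+00 7.45966888e-20 9.13217967e-25 6.89354136e-22
4.16179145e+00 5.71637299e-20 1.09319416e-24 6.32827825e-22
4.57683934e+00 4.38047864e-20 1.30618166e-24 5.80936612e-22
5.03327921e+00 3.35677765e-20 1.55721474e-24 5.33300424e-22
5.53523899e+00 2.57231164e-20 1.85167853e-24 4.89570353e-22
6.08725830e+00 1.97117232e-20 2.19515501e-24 4.49426101e-22
6.69432950e+00 1.51051694e-20 2.59318604e-24 4.12573636e-22
7.36194281e+00 1.15751495e-20 3.05093971e-24 3.78743034e-22
8.09613597e+00 8.87008161e-21 3.57277340e-24 3.47686505e-22
8.90354889e+00 6.79717770e-21 4.16170121e-24 3.19176579e-22
9.79148362e+00 5.20870344e-21 4.81879468e-24 2.93004437e-22
1.07679705e+01 3.99144951e-21 5.54257233e-24 2.55023970e-22
1.18418406e+01 3.05866313e-21 6.32846147e-24 2.18624449e-22
1.18658133e+01 3.04139205e-21 6.34580277e-24 2.17909358e-22
1.18670000e+01 2.25000000e-20 6.34666093e-24 2.17874058e-22
1.30228058e+01 1.67582952e-20 7.16843635e-24 1.87420225e-22
1.43215465e+01 1.23981036e-20 8.05093982e-24 1.60669773e-22
1.57498083e+01 9.17235151e-21 8.96117180e-24 1.37737408e-22
1.73205081e+01 6.78587908e-21 9.88177436e-24 1.18078175e-22
1.90478508e+01 5.02032166e-21 1.07938683e-23 1.01224901e-22
2.09474584e+01 3.71412889e-21 1.16783180e-23 8.67770905e-23
2.30365103e+01 2.74778278e-21 1.25170473e-23 7.43914136e-23
2.53338996e+01 2.03286166e-21 1.32942119e-23 6.37735418e-23
2.78604033e+01 1.50394949e-21 1.39970724e-23 5.46711568e-23
3.06388706e+01 1.11546734e-21 1.46164751e-23 4.65431738e-23
3.36944295e+01 8.34711752e-22 1.51469336e-23 3.86678081e-23
3.70547136e+01 6.24620448e-22 1.55863707e-23 3.21249983e-23
4.07501128e+01 4.67407705e-22 1.59356233e-23 2.66892686e-23
4.48140475e+01 3.49764346e-22 1.61978246e-23 2.21732948e-23
4.92832709e+01 2.61731025e-22 1.63777636e-23 1.84214491e-23
5.41982019e+01 1.95855096e-22 1.64812965e-23 1.53044367e-23
5.96032900e+01 1.46559693e-22 1.65148508e-23 1.27148403e-23
6.55474177e+01 1.09671609e-22 1.64850421e-23 1.05634181e-23
7.20843424e+01 8.20680066e-23 1.63983992e-23 8.77602856e-24
7.92731828e+01 6.14120443e-23 1.62611835e-23 7.29107536e-24
8.71789531e+01 4.59550480e-23 1.60792855e-23 6.05738456e-24
9.58731516e+01 3.43884731e-23 1.58581770e-23 5.03244116e-24
1.05434407e+02 2.61449172e-23 1.56029017e-23 4.18092392e-24
1.15949188e+02 2.01304066e-23 1.53180896e-23 3.47348817e-24
1.27512590e+02 1.54995048e-23 1.50079838e-23 2.88575451e-24
1.40229188e+02 1.19339193e-23 1.46764705e-23 2.39746868e-24
1.54213990e+02 9.18857942e-24 1.43271097e-23 1.99180355e-24
1.69593471e+02 7.07479157e-24 1.39631603e-23 1.65477923e-24
1.86506720e+02 5.44727029e-24 1.35876009e-23 1.37478131e-24
2.05106696e+02 4.19415234e-24 1.32031447e-23 1.14216061e-24
2.25561613e+02 3.22930806e-24 1.28122515e-23 9.48900638e-25
2.48056463e+02 2.48642150e-24 1.24171351e-23 7.88341334e-25
2.72794682e+02 1.91443237e-24 1.20197710e-23 6.54949564e-25
3.00000000e+02 1.47402654e-24 1.16219033e-23 5.44128428e-25
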