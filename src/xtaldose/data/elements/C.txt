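# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 4.90980911e-20 1.15340154e-25 2.70071600e-23
1.09972818e+00 3.65662150e-20 1.38596612e-25 2.47926014e-23
1.20940207e+00 2.72329953e-20 1.66332988e-25 2.27596343e-23
1.33001354e+00 2.02820016e-20 1.99321726e-25 2.08933683e-23
1.46265337e+00 1.51051908e-20 2.38429892e-25 1.91801342e-23
1.60852113e+00 1.12497175e-20 2.84614130e-25 1.76073835e-23
1.76893602e+00 8.37832143e-21 3.38906944e-25 1.61635966e-23
1.94534879e+00 6.23982515e-21 4.02391229e-25 1.48381988e-23
2.13935489e+00 4.64716210e-21 4.76159801e-25 1.36214822e-23
2.35270886e+00 3.46101294e-21 5.61257100e-25 1.25045350e-23
2.58734024e+00 2.57761841e-21 6.58601454e-25 1.14791764e-23
2.84537097e+00 1.91970293e-21 7.68888773e-25 1.05378960e-23
3.12913464e+00 1.42971485e-21 8.92482236e-25 9.67379971e-24
3.44119755e+00 1.06479213e-21 1.02929747e-24 8.88055835e-24
3.78438192e+00 7.93012865e-22 1.17869795e-24 8.15236195e-24
4.16179145e+00 5.90602981e-22 1.33941952e-24 7.48387689e-24
4.57683934e+00 4.39856523e-22 1.50954409e-24 6.87020689e-24
5.03327921e+00 3.27586834e-22 1.68653899e-24 6.30685719e-24
5.53523899e+00 2.43973041e-22 1.86736919e-24 5.78970157e-24
6.08725830e+00 1.81700968e-22 2.04867646e-24 5.31495216e-24
6.69432950e+00 1.35323320e-22 2.22700438e-24 4.87913170e-24
7.36194281e+00 1.00783177e-22 2.39903823e-24 4.47904805e-24
8.09613597e+00 7.50591164e-23 2.56182394e-24 4.11177085e-24
8.90354889e+00 5.59009063e-23 2.71293624e-24 3.77460998e-24
9.79148362e+00 4.16326688e-23 2.85057729e-24 3.46509595e-24
1.07679705e+01 3.08461015e-23 2.97360223e-24 3.01593564e-24
1.18418406e+01 2.28205291e-23 3.08148093e-24 2.58547175e-24
1.30228058e+01 1.68830590e-23 3.17421366e-24 2.21644788e-24
1.43215465e+01 1.24904063e-23 3.25222110e-24 1.90009471e-24
1.57498083e+01 9.24063872e-24 3.31622761e-24 1.62889457e-24
1.73205081e+01 6.83639926e-24 3.36715151e-24 1.39640277e-24
1.90478508e+01 5.05769744e-24 3.40601147e-24 1.19709448e-24
2.09474584e+01 3.74178020e-24 3.43385250e-24 1.02623342e-24
2.30365103e+01 2.76823974e-24 3.45169209e-24 8.79759326e-25
2.53338996e+01 2.04799611e-24 3.46048432e-24 7.54191451e-25
2.78604033e+01 1.51514624e-24 3.46109900e-24 6.46545854e-25
3.06388706e+01 1.12377188e-24 3.45431231e-24 5.50423621e-25
3.36944295e+01 8.40926096e-25 3.44080597e-24 4.57288861e-25
3.70547136e+01 6.29270684e-25 3.42117214e-24 3.79913024e-25
4.07501128e+01 4.70887508e-25 3.39592209e-24 3.15629611e-25
4.48140475e+01 3.52368306e-25 3.36549683e-24 2.62223313e-25
4.92832709e+01 2.63679586e-25 3.33027871e-24 2.17853659e-25
5.41982019e+01 1.97313217e-25 3.29060312e-24 1.80991600e-25
5.96032900e+01 1.47650815e-25 3.24676961e-24 1.50366807e-25
6.55474177e+01 1.10488103e-25 3.19905225e-24 1.24923901e-25
7.20843424e+01 8.26789945e-26 3.14770874e-24 1.03786077e-25
7.92731828e+01 6.18692506e-26 3.09298828e-24 8.62248913e-26
8.71789531e+01 4.62971786e-26 3.03513800e-24 7.16351566e-26
9.58731516e+01 3.46444918e-26 2.97440788e-24 5.95140868e-26
1.05434407e+02 2.63395634e-26 2.91105415e-24 4.94439699e-26
1.15949188e+02 2.02802754e-26 2.84534114e-24 4.10777731e-26
1.27512590e+02 1.56148970e-26 2.77754177e-24 3.41271838e-26
1.40229188e+02 1.20227661e-26 2.70793654e-24 2.83526731e-26
1.54213990e+02 9.25698746e-27 2.63681153e-24 2.35552420e-26
1.69593471e+02 7.12746266e-27 2.56445519e-24 1.95695631e-26
1.86506720e+02 5.48782466e-27 2.49115467e-24 1.62582834e-26
2.05106696e+02 4.22537738e-27 2.41719151e-24 1.35072907e-26
2.25561613e+02 3.25334993e-27 2.34283737e-24 1.12217815e-26
2.48056463e+02 2.50493265e-27 2.26834991e-24 9.32299317e-27
2.72794682e+02 1.92868512e-27 2.19396911e-24 7.74549049e-27
3.00000000e+02 1.48500052e-27 2.11991441e-24 6.43491011e-27
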