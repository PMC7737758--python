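# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 4.64795981e-19 8.03742295e-26 5.43320513e-22
1.09972818e+00 3.56174950e-19 9.70373571e-26 4.98768805e-22
1.20940207e+00 2.72938236e-19 1.17118087e-25 4.57870290e-22
1.33001354e+00 2.09153621e-19 1.41301074e-25 4.20325410e-22
1.46265337e+00 1.60275225e-19 1.70400917e-25 3.85859171e-22
1.60852113e+00 1.22819522e-19 2.05383603e-25 3.54219126e-22
1.76893602e+00 9.41170730e-20 2.47390027e-25 3.25173532e-22
1.94534879e+00 7.21222755e-20 2.97761067e-25 2.98509646e-22
2.13935489e+00 5.52675775e-20 3.58063222e-25 2.74032171e-22
2.35270886e+00 4.23517575e-20 4.30113204e-25 2.51561822e-22
2.58734024e+00 3.24543148e-20 5.15998995e-25 2.30934019e-22
2.84537097e+00 2.48698664e-20 6.18093734e-25 2.11997673e-22
3.12913464e+00 1.90578744e-20 7.39057428e-25 1.94614088e-22
3.44119755e+00 1.46041226e-20 8.81819869e-25 1.78655939e-22
3.60763920e+00 1.27949234e-20 9.61830563e-25 1.71220324e-22
3.60800000e+00 1.20238607e-19 9.62006781e-25 1.71204914e-22
3.78438192e+00 1.03701682e-19 1.04953652e-24 1.64006340e-22
4.16179145e+00 7.72326975e-20 1.24550784e-24 1.50557994e-22
4.57683934e+00 5.75196991e-20 1.47305196e-24 1.38212398e-22
5.03327921e+00 4.28382782e-20 1.73532207e-24 1.26879127e-22
5.53523899e+00 3.19041669e-20 2.03506342e-24 1.16475173e-22
6.08725830e+00 2.37608959e-20 2.37431266e-24 1.06924332e-22
6.69432950e+00 1.76961264e-20 2.75405348e-24 9.81566494e-23
7.36194281e+00 1.31793386e-20 3.17385821e-24 9.01079079e-23
8.09613597e+00 9.81542291e-21 3.63156089e-24 8.27191547e-23
8.90354889e+00 7.31011852e-21 4.12302091e-24 7.59362714e-23
9.79148362e+00 5.44427207e-21 4.64204018e-24 6.97095774e-23
1.07679705e+01 4.03372096e-21 5.18048588e-24 6.06735288e-23
1.18418406e+01 2.98422304e-21 5.72864274e-24 5.20136081e-23
1.30228058e+01 2.20778463e-21 6.27577671e-24 4.45897161e-23
1.43215465e+01 1.63336082e-21 6.81084626e-24 3.82254347e-23
1.57498083e+01 1.20839122e-21 7.32326240e-24 3.27695260e-23
1.73205081e+01 8.93990672e-22 7.80358579e-24 2.80923380e-23
1.90478508e+01 6.61391203e-22 8.24406442e-24 2.40827242e-23
2.09474584e+01 4.89309718e-22 8.63895218e-24 2.06454017e-23
2.30365103e+01 3.62000582e-22 8.98459520e-24 1.76986876e-23
2.53338996e+01 2.67814875e-22 9.27931470e-24 1.51725574e-23
2.78604033e+01 1.98134509e-22 9.52314245e-24 1.30069813e-23
3.06388706e+01 1.46954784e-22 9.71747413e-24 1.10732281e-23
3.36944295e+01 1.09967259e-22 9.86470047e-24 9.19957590e-24
3.70547136e+01 8.22892433e-23 9.96786149e-24 7.64295612e-24
4.07501128e+01 6.15775971e-23 1.00303518e-23 6.34972513e-24
4.48140475e+01 4.60789323e-23 1.00556891e-23 5.27531606e-24
4.92832709e+01 3.44811766e-23 1.00473472e-23 4.38270303e-24
5.41982019e+01 2.58024976e-23 1.00086458e-23 3.64112512e-24
5.96032900e+01 1.93081834e-23 9.94268783e-24 3.02502635e-24
6.55474177e+01 1.44484442e-23 9.85233179e-24 2.51317495e-24
7.20843424e+01 1.08118685e-23 9.74019021e-24 2.08793167e-24
7.92731828e+01 8.09059431e-24 9.60864384e-24 1.73464193e-24
8.71789531e+01 6.05424643e-24 9.45986509e-24 1.44113080e-24
9.58731516e+01 4.53043354e-24 9.29584528e-24 1.19728339e-24
1.05434407e+02 3.44440444e-24 9.11842169e-24 9.94696335e-25
1.15949188e+02 2.65203601e-24 8.92930198e-24 8.26388142e-25
1.27512590e+02 2.04194807e-24 8.73008427e-24 6.86558639e-25
1.40229188e+02 1.57220788e-24 8.52227233e-24 5.70389071e-25
1.54213990e+02 1.21052913e-24 8.30728561e-24 4.73876044e-25
1.69593471e+02 9.32052810e-25 8.08646459e-24 3.93693563e-25
1.86506720e+02 7.17638609e-25 7.86107210e-24 3.27078406e-25
2.05106696e+02 5.52549349e-25 7.63229163e-24 2.71734908e-25
2.25561613e+02 4.25438068e-25 7.40122369e-24 2.25755839e-25
2.48056463e+02 3.27568116e-25 7.16888141e-24 1.87556686e-25
2.72794682e+02 2.52212670e-25 6.93618625e-24 1.55821044e-25
3.00000000e+02 1.94192376e-25 6.70396495e-24 1.29455250e-25
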