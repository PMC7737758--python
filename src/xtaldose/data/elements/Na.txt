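# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 6.18884422e-20 9.57798185e-26 1.31064159e-22
1.07089290e+00 5.10882047e-20 1.09599702e-25 1.23228882e-22
1.07100000e+00 5.61812914e-19 1.09621250e-25 1.23217792e-22
1.09972818e+00 5.17552582e-19 1.15473672e-25 1.20317036e-22
1.20940207e+00 3.85451625e-19 1.39132872e-25 1.10451166e-22
1.33001354e+00 2.87068330e-19 1.67518685e-25 1.01394287e-22
1.46265337e+00 2.13796546e-19 2.01522155e-25 9.30800631e-23
1.60852113e+00 1.59226771e-19 2.42178975e-25 8.54475963e-23
1.76893602e+00 1.18585473e-19 2.90682715e-25 7.84409837e-23
1.94534879e+00 8.83175251e-20 3.48394414e-25 7.20089059e-23
2.13935489e+00 6.57752174e-20 4.16845804e-25 6.61042517e-23
2.35270886e+00 4.89866448e-20 4.97732498e-25 6.06837730e-23
2.58734024e+00 3.64832145e-20 5.92892487e-25 5.57077677e-23
2.84537097e+00 2.71711799e-20 7.04264503e-25 5.11397896e-23
3.12913464e+00 2.02359641e-20 8.33820345e-25 4.69463809e-23
3.44119755e+00 1.50709039e-20 9.83465755e-25 4.30968273e-23
3.78438192e+00 1.12241821e-20 1.15490630e-24 3.95629330e-23
4.16179145e+00 8.35930373e-21 1.34947863e-24 3.63188143e-23
4.57683934e+00 6.22566155e-21 1.56795380e-24 3.33407099e-23
5.03327921e+00 4.63661365e-21 1.81032776e-24 3.06068069e-23
5.53523899e+00 3.45315689e-21 2.07562392e-24 2.80970811e-23
6.08725830e+00 2.57176755e-21 2.36174090e-24 2.57931502e-23
6.69432950e+00 1.91534545e-21 2.66538211e-24 2.36781391e-23
7.36194281e+00 1.42646959e-21 2.98209979e-24 2.17365567e-23
8.09613597e+00 1.06237519e-21 3.30647133e-24 1.99541821e-23
8.90354889e+00 7.91212828e-22 3.63240267e-24 1.83179602e-23
9.79148362e+00 5.89262389e-22 3.95352669e-24 1.68159068e-23
1.07679705e+01 4.36590975e-22 4.26364252e-24 1.46361583e-23
1.18418406e+01 3.22998259e-22 4.55713117e-24 1.25471423e-23
1.30228058e+01 2.38960219e-22 4.82928869e-24 1.07562912e-23
1.43215465e+01 1.76787289e-22 5.07653735e-24 9.22104785e-24
1.57498083e+01 1.30790579e-22 5.29650182e-24 7.90492951e-24
1.73205081e+01 9.67613433e-23 5.48796286e-24 6.77666049e-24
1.90478508e+01 7.15858714e-23 5.65071827e-24 5.80942908e-24
2.09474584e+01 5.29605813e-23 5.78538879e-24 4.98025041e-24
2.30365103e+01 3.91812394e-23 5.89320440e-24 4.26942026e-24
2.53338996e+01 2.89870218e-23 5.97579935e-24 3.66004675e-24
2.78604033e+01 2.14451468e-23 6.03503390e-24 3.13764900e-24
3.06388706e+01 1.59056943e-23 6.07285179e-24 2.67117346e-24
3.36944295e+01 1.19023386e-23 6.09117510e-24 2.21919594e-24
3.70547136e+01 8.90660045e-24 6.09183343e-24 1.84369556e-24
4.07501128e+01 6.66486934e-24 6.07652184e-24 1.53173194e-24
4.48140475e+01 4.98736679e-24 6.04678141e-24 1.27255431e-24
4.92832709e+01 3.73208029e-24 6.00399620e-24 1.05723099e-24
5.41982019e+01 2.79274092e-24 5.94940143e-24 8.78341586e-25
5.96032900e+01 2.08982691e-24 5.88409868e-24 7.29721269e-25
6.55474177e+01 1.56383161e-24 5.80907471e-24 6.06248342e-25
7.20843424e+01 1.17022577e-24 5.72522150e-24 5.03667726e-25
7.92731828e+01 8.75687855e-25 5.63335581e-24 4.18444325e-25
8.71789531e+01 6.55283143e-25 5.53423697e-24 3.47641201e-25
9.58731516e+01 4.90352807e-25 5.42858227e-24 2.88818362e-25
1.05434407e+02 3.72806128e-25 5.31707922e-24 2.39948677e-25
1.15949188e+02 2.87043898e-25 5.20039479e-24 1.99348017e-25
1.27512590e+02 2.21010850e-25 5.07918135e-24 1.65617215e-25
1.40229188e+02 1.70168382e-25 4.95407954e-24 1.37593855e-25
1.54213990e+02 1.31021976e-25 4.82571848e-24 1.14312204e-25
1.69593471e+02 1.00881010e-25 4.69471356e-24 9.49699384e-26
1.86506720e+02 7.76738259e-26 4.56166248e-24 7.89004927e-26
2.05106696e+02 5.98053413e-26 4.42714003e-24 6.55500873e-26
2.25561613e+02 4.60474144e-26 4.29169236e-24 5.44586453e-26
2.48056463e+02 3.54544314e-26 4.15583120e-24 4.52439374e-26
2.72794682e+02 2.72983125e-26 4.02002871e-24 3.75884097e-26
3.00000000e+02 2.10184689e-26 3.88471342e-24 3.12282402e-26
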