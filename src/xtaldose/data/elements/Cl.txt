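# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 3.04331451e-19 8.33250156e-26 4.07490384e-22
1.09972818e+00 2.33210363e-19 1.00578592e-25 3.74076604e-22
1.20940207e+00 1.78709999e-19 1.21361144e-25 3.43402717e-22
1.33001354e+00 1.36946161e-19 1.46375217e-25 3.15244057e-22
1.46265337e+00 1.04942370e-19 1.76454680e-25 2.89394378e-22
1.60852113e+00 8.04177425e-20 2.12585476e-25 2.65664345e-22
1.76893602e+00 6.16244258e-20 2.55927909e-25 2.43880149e-22
1.94534879e+00 4.72230348e-20 3.07839700e-25 2.23882235e-22
2.13935489e+00 3.61871934e-20 3.69898521e-25 2.05524128e-22
2.35270886e+00 2.77303857e-20 4.43921969e-25 1.88671367e-22
2.58734024e+00 2.12499013e-20 5.31981979e-25 1.73200514e-22
2.82171780e+00 1.66689721e-20 6.26519848e-25 1.60197283e-22
2.82200000e+00 1.66643052e-19 6.26637470e-25 1.60182865e-22
2.84537097e+00 1.62436402e-19 6.36409498e-25 1.58998255e-22
3.12913464e+00 1.20975872e-19 7.59783817e-25 1.45960566e-22
3.44119755e+00 9.00977953e-20 9.04899494e-25 1.33991954e-22
3.78438192e+00 6.71010886e-20 1.07470252e-24 1.23004755e-22
4.16179145e+00 4.99740984e-20 1.27218676e-24 1.12918495e-22
4.57683934e+00 3.72186288e-20 1.50024228e-24 1.03659298e-22
5.03327921e+00 2.77188859e-20 1.76145016e-24 9.51593452e-23
5.53523899e+00 2.06438727e-20 2.05782416e-24 8.73563795e-23
6.08725830e+00 1.53746973e-20 2.39050929e-24 8.01932487e-23
6.69432950e+00 1.14504348e-20 2.75946019e-24 7.36174871e-23
7.36194281e+00 8.52780731e-21 3.16313717e-24 6.75809309e-23
8.09613597e+00 6.35115600e-21 3.59827052e-24 6.20393660e-23
8.90354889e+00 4.73007669e-21 4.05974972e-24 5.69522036e-23
9.79148362e+00 3.52276428e-21 4.54068784e-24 5.22821831e-23
1.07679705e+01 2.61005474e-21 5.03268946e-24 4.55051466e-23
1.18418406e+01 1.93096785e-21 5.52631538e-24 3.90102061e-23
1.30228058e+01 1.42856653e-21 6.01169571e-24 3.34422871e-23
1.43215465e+01 1.05688053e-21 6.47920862e-24 2.86690760e-23
1.57498083e+01 7.81900200e-22 6.92012529e-24 2.45771445e-23
1.73205081e+01 5.78464553e-22 7.32712951e-24 2.10692535e-23
1.90478508e+01 4.27959014e-22 7.69464986e-24 1.80620431e-23
2.09474584e+01 3.16612171e-22 8.01898314e-24 1.54840513e-23
2.30365103e+01 2.34235671e-22 8.29822732e-24 1.32740157e-23
2.53338996e+01 1.73291978e-22 8.53206983e-24 1.13794181e-23
2.78604033e+01 1.28204682e-22 8.72148909e-24 9.75523598e-24
3.06388706e+01 9.50883898e-23 8.86842489e-24 8.30492111e-24
3.36944295e+01 7.11552850e-23 8.97546146e-24 6.89968193e-24
3.70547136e+01 5.32459809e-23 9.04555174e-24 5.73221709e-24
4.07501128e+01 3.98443276e-23 9.08179692e-24 4.76229384e-24
4.48140475e+01 2.98157797e-23 9.08728393e-24 3.95648705e-24
4.92832709e+01 2.23113496e-23 9.06497599e-24 3.28702727e-24
5.41982019e+01 1.66957338e-23 9.01764762e-24 2.73084384e-24
5.96032900e+01 1.24935305e-23 8.94785424e-24 2.26876976e-24
6.55474177e+01 9.34899332e-24 8.85792651e-24 1.88488121e-24
7.20843424e+01 6.99591492e-24 8.74998132e-24 1.56594875e-24
7.92731828e+01 5.23509044e-24 8.62594257e-24 1.30098145e-24
8.71789531e+01 3.91745357e-24 8.48756653e-24 1.08084810e-24
9.58731516e+01 2.93145700e-24 8.33646798e-24 8.97962544e-25
1.05434407e+02 2.22873229e-24 8.17414464e-24 7.46022251e-25
1.15949188e+02 1.71602330e-24 8.00199796e-24 6.19791107e-25
1.27512590e+02 1.32126051e-24 7.82134964e-24 5.14918979e-25
1.40229188e+02 1.01731098e-24 7.63345335e-24 4.27791803e-25
1.54213990e+02 7.83283554e-25 7.43950172e-24 3.55407033e-25
1.69593471e+02 6.03092995e-25 7.24062930e-24 2.95270172e-25
1.86506720e+02 4.64354394e-25 7.03791196e-24 2.45308805e-25
2.05106696e+02 3.57531932e-25 6.83236378e-24 2.03801181e-25
2.25561613e+02 2.75283456e-25 6.62493239e-24 1.69316879e-25
2.48056463e+02 2.11955840e-25 6.41649374e-24 1.40667515e-25
2.72794682e+02 1.63196433e-25 6.20784722e-24 1.16865783e-25
3.00000000e+02 1.25653890e-25 5.99971207e-24 9.70914378e-26
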