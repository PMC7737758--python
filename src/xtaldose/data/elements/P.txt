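# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 2.09770526e-19 8.67584125e-26 2.93901447e-22
1.09972818e+00 1.60747962e-19 1.04693772e-25 2.69801839e-22
1.20940207e+00 1.23181782e-19 1.26284278e-25 2.47678373e-22
1.33001354e+00 9.43946740e-20 1.52251573e-25 2.27369008e-22
1.46265337e+00 7.23350022e-20 1.83449466e-25 2.08724990e-22
1.60852113e+00 5.54305907e-20 2.20883555e-25 1.91609761e-22
1.76893602e+00 4.24766752e-20 2.65731652e-25 1.75897963e-22
1.94534879e+00 3.25500397e-20 3.19363951e-25 1.61474516e-22
2.13935489e+00 2.49432208e-20 3.83361226e-25 1.48233777e-22
2.14578540e+00 2.47344846e-20 3.85569812e-25 1.47833911e-22
2.14600000e+00 2.59639376e-19 3.85643613e-25 1.47820606e-22
2.35270886e+00 1.95236628e-19 4.59528548e-25 1.36078764e-22
2.58734024e+00 1.45404116e-19 5.49900954e-25 1.24920449e-22
2.84537097e+00 1.08290934e-19 6.56736303e-25 1.14677104e-22
3.12913464e+00 8.06505815e-20 7.82489230e-25 1.05273703e-22
3.44119755e+00 6.00651969e-20 9.29758930e-25 9.66413703e-23
3.78438192e+00 4.47340590e-20 1.10120285e-24 8.87168801e-23
4.16179145e+00 3.33160656e-20 1.29940872e-24 8.14421897e-23
4.57683934e+00 2.48124192e-20 1.52671964e-24 7.47640162e-23
5.03327921e+00 1.84792573e-20 1.78501166e-24 6.86334459e-23
5.53523899e+00 1.37625818e-20 2.07543140e-24 6.30055759e-23
6.08725830e+00 1.02497982e-20 2.39811253e-24 5.78391852e-23
6.69432950e+00 7.63362317e-21 2.75190241e-24 5.30964332e-23
7.36194281e+00 5.68520487e-21 3.13414285e-24 4.87425818e-23
8.09613597e+00 4.23410400e-21 3.54055464e-24 4.47457416e-23
8.90354889e+00 3.15338446e-21 3.96527163e-24 4.10766380e-23
9.79148362e+00 2.34850952e-21 4.40105312e-24 3.77083971e-23
1.07679705e+01 1.74003649e-21 4.83967256e-24 3.28204761e-23
1.18418406e+01 1.28731190e-21 5.27244497e-24 2.81360161e-23
1.30228058e+01 9.52377685e-22 5.69082312e-24 2.41201681e-23
1.43215465e+01 7.04587020e-22 6.08697527e-24 2.06775012e-23
1.57498083e+01 5.21266800e-22 6.45426185e-24 1.77262056e-23
1.73205081e+01 3.85643035e-22 6.78755189e-24 1.51961478e-23
1.90478508e+01 2.85306009e-22 7.08335568e-24 1.30272046e-23
2.09474584e+01 2.11074780e-22 7.33978562e-24 1.11678343e-23
2.30365103e+01 1.56157114e-22 7.55638323e-24 9.57385148e-24
2.53338996e+01 1.15527985e-22 7.73386295e-24 8.20737755e-24
2.78604033e+01 8.54697881e-23 7.87382225e-24 7.03594018e-24
3.06388706e+01 6.33922599e-23 7.97845873e-24 5.98990411e-24
3.36944295e+01 4.74368567e-23 8.05032089e-24 4.97637878e-24
3.70547136e+01 3.54973206e-23 8.09210668e-24 4.13434761e-24
4.07501128e+01 2.65628850e-23 8.10651325e-24 3.43479283e-24
4.48140475e+01 1.98771865e-23 8.09613444e-24 2.85360664e-24
4.92832709e+01 1.48742331e-23 8.06339870e-24 2.37076041e-24
5.41982019e+01 1.11304892e-23 8.01053882e-24 1.96961447e-24
5.96032900e+01 8.32902031e-24 7.93958484e-24 1.63634466e-24
6.55474177e+01 6.23266222e-24 7.85237279e-24 1.35946598e-24
7.20843424e+01 4.66394328e-24 7.75056305e-24 1.12943672e-24
7.92731828e+01 3.49006029e-24 7.63566358e-24 9.38329699e-25
8.71789531e+01 2.61163572e-24 7.50905455e-24 7.79559057e-25
9.58731516e+01 1.95430467e-24 7.37201182e-24 6.47653297e-25
1.05434407e+02 1.48582153e-24 7.22572773e-24 5.38066731e-25
1.15949188e+02 1.14401553e-24 7.07132805e-24 4.47022825e-25
1.27512590e+02 8.80840343e-25 6.90988472e-24 3.71384059e-25
1.40229188e+02 6.78207320e-25 6.74242431e-24 3.08543796e-25
1.54213990e+02 5.22189036e-25 6.56993236e-24 2.56336457e-25
1.69593471e+02 4.02061996e-25 6.39335415e-24 2.12962892e-25
1.86506720e+02 3.09569596e-25 6.21359260e-24 1.76928378e-25
2.05106696e+02 2.38354621e-25 6.03150409e-24 1.46991105e-25
2.25561613e+02 1.83522304e-25 5.84789310e-24 1.22119386e-25
2.48056463e+02 1.41303893e-25 5.66350645e-24 1.01456102e-25
2.72794682e+02 1.08797622e-25 5.47902814e-24 8.42891612e-26
3.00000000e+02 8.37692602e-26 5.29507530e-24 7.00269629e-26
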