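# energy_keV photoelectric_cm2 incoherent_cm2 coherent_cm2
# per-atom cross sections, 1-300 keV; table version 1
1.00000000e+00 1.76627235e-19 1.05771006e-25 5.73504985e-23
1.09972818e+00 1.31544615e-19 1.27338060e-25 5.26478183e-23
1.20940207e+00 9.79689548e-20 1.53166581e-25 4.83307528e-23
1.33001354e+00 7.29632006e-20 1.84038875e-25 4.43676822e-23
1.46265337e+00 5.43399555e-20 2.20854886e-25 4.07295791e-23
1.60852113e+00 4.04701375e-20 2.64638532e-25 3.73897967e-23
1.76893602e+00 3.01404743e-20 3.16538888e-25 3.43238729e-23
1.94534879e+00 2.24473710e-20 3.77823380e-25 3.15093516e-23
2.13935489e+00 1.67178678e-20 4.49859468e-25 2.89256180e-23
2.35270886e+00 1.24507722e-20 5.34080703e-25 2.65537479e-23
2.58734024e+00 9.27281701e-21 6.31932877e-25 2.43763687e-23
2.84537097e+00 6.90600823e-21 7.44796468e-25 2.23775322e-23
3.12913464e+00 5.14330754e-21 8.73883284e-25 2.05425982e-23
3.44119755e+00 3.83052142e-21 1.02010840e-24 1.88581269e-23
3.78438192e+00 2.85281295e-21 1.18394345e-24 1.73117804e-23
4.16179145e+00 2.12465636e-21 1.36526392e-24 1.58922327e-23
4.57683934e+00 1.58235564e-21 1.56320989e-24 1.45890864e-23
5.03327921e+00 1.17847263e-21 1.77608544e-24 1.33927967e-23
5.53523899e+00 8.77677377e-22 2.00132342e-24 1.22946016e-23
6.08725830e+00 6.53657586e-22 2.23553760e-24 1.12864572e-23
6.69432950e+00 4.86816969e-22 2.47467173e-24 1.03609797e-23
7.36194281e+00 3.62561020e-22 2.71423789e-24 9.51139028e-24
8.09613597e+00 2.70020360e-22 2.94961648e-24 8.73146633e-24
8.90354889e+00 2.01099927e-22 3.17637591e-24 8.01549532e-24
9.79148362e+00 1.49770857e-22 3.39056502e-24 7.35823317e-24
1.07679705e+01 1.10966873e-22 3.58893773e-24 6.40442805e-24
1.18418406e+01 8.20953907e-23 3.76908530e-24 5.49032530e-24
1.30228058e+01 6.07357224e-23 3.92947090e-24 4.70669225e-24
1.43215465e+01 4.49334358e-23 4.06937905e-24 4.03490700e-24
1.57498083e+01 3.32426055e-23 4.18880344e-24 3.45900552e-24
1.73205081e+01 2.45935081e-23 4.28830048e-24 2.96530235e-24
1.90478508e+01 1.81947423e-23 4.36883366e-24 2.54206533e-24
2.09474584e+01 1.34608144e-23 4.43162747e-24 2.17923685e-24
2.30365103e+01 9.95856502e-24 4.47804269e-24 1.86819480e-24
2.53338996e+01 7.36753471e-24 4.50947812e-24 1.60154773e-24
2.78604033e+01 5.45064149e-24 4.52729911e-24 1.37295914e-24
3.06388706e+01 4.04269730e-24 4.53279034e-24 1.16884075e-24
3.36944295e+01 3.02517772e-24 4.52712848e-24 9.71066345e-25
3.70547136e+01 2.26376095e-24 4.51137043e-24 8.06756479e-25
4.07501128e+01 1.69398762e-24 4.48645274e-24 6.70248763e-25
4.48140475e+01 1.26762239e-24 4.45319867e-24 5.56838917e-25
4.92832709e+01 9.48570408e-25 4.41233010e-24 4.62618653e-25
5.41982019e+01 7.09821650e-25 4.36448189e-24 3.84340985e-25
5.96032900e+01 5.31164341e-25 4.31021728e-24 3.19308337e-25
6.55474177e+01 3.97473868e-25 4.25004310e-24 2.65279578e-25
7.20843424e+01 2.97432383e-25 4.18442390e-24 2.20392787e-25
7.92731828e+01 2.22570663e-25 4.11379471e-24 1.83101093e-25
8.71789531e+01 1.66551132e-25 4.03857177e-24 1.52119362e-25
9.58731516e+01 1.24631338e-25 3.95916123e-24 1.26379914e-25
1.05434407e+02 9.47548909e-26 3.87596569e-24 1.04995724e-25
1.15949188e+02 7.29569906e-26 3.78938842e-24 8.72298594e-26
1.27512590e+02 5.61735910e-26 3.69983549e-24 7.24700785e-26
1.40229188e+02 4.32511305e-26 3.60771595e-24 6.02077352e-26
1.54213990e+02 3.33014190e-26 3.51344009e-24 5.00202491e-26
1.69593471e+02 2.56405900e-26 3.41741642e-24 4.15565427e-26
1.86506720e+02 1.97420974e-26 3.32004740e-24 3.45249429e-26
2.05106696e+02 1.52005243e-26 3.22172456e-24 2.86831291e-26
2.25561613e+02 1.17037178e-26 3.12282330e-24 2.38297830e-26
2.48056463e+02 9.01133465e-27 3.02369798e-24 1.97976502e-26
2.72794682e+02 6.93832109e-27 2.92467741e-24 1.64477769e-26
3.00000000e+02 5.34219418e-27 2.82606136e-24 1.36647209e-26
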