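# symbol Z mass_g_mol k_binding_keV k_fluor_yield k_alpha_keV l_binding_keV k_shell_fraction mean_excitation_eV
# table version 1; mean excitation energies are in-compound (Bragg-additivity) values
H 1 1.008 0.0136 0.0 0.0 0.0 1.0 19.2
C 6 12.011 0.284 0.0028 0.277 0.007 0.93 81.0
N 7 14.007 0.41 0.0052 0.392 0.009 0.93 82.0
O 8 15.999 0.543 0.0083 0.525 0.0285 0.93 106.0
F 9 18.998 0.697 0.013 0.677 0.031 0.93 112.0
Na 11 22.99 1.071 0.023 1.041 0.063 0.93 168.0
P 15 30.974 2.146 0.063 2.014 0.132 0.93 173.0
S 16 32.06 2.472 0.078 2.308 0.165 0.93 180.0
Cl 17 35.45 2.822 0.097 2.622 0.202 0.93 174.0
K 19 39.098 3.608 0.14 3.314 0.297 0.93 190.0
Fe 26 55.845 7.112 0.34 6.404 0.723 0.93 286.0
Cu 29 63.546 8.979 0.44 8.048 0.952 0.93 322.0
As 33 74.922 11.867 0.562 10.544 1.359 0.93 347.0
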