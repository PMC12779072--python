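# Photon mass attenuation reference for H, C, N, O, 0.015-15 MeV.
# total_mu_rho_cm2_g: transcribed from the NIST/XCOM standard photon
#   cross-section tabulation (total attenuation with coherent scattering).
# compton_mu_rho_cm2_g: incoherent channel estimated from the
#   Klein-Nishina free-electron cross section, sigma_KN * N_A * Z / A
#   (binding effects neglected; adequate for Compton/total ratio work
#   above ~0.1 MeV, approximate below).
element,Z,energy_MeV,total_mu_rho_cm2_g,compton_mu_rho_cm2_g
H,1,0.015,0.3764,0.375764
H,1,0.02,0.3695,0.369207
H,1,0.03,0.357,0.356964
H,1,0.04,0.3458,0.345758
H,1,0.05,0.3355,0.335464
H,1,0.06,0.326,0.325972
H,1,0.08,0.3091,0.309044
H,1,0.1,0.2944,0.294385
H,1,0.15,0.2651,0.265025
H,1,0.2,0.2429,0.242847
H,1,0.3,0.2112,0.211163
H,1,0.4,0.1893,0.189195
H,1,0.5,0.1729,0.172758
H,1,0.6,0.1599,0.159812
H,1,0.8,0.1405,0.140373
H,1,1.0,0.1263,0.126183
H,1,1.25,0.1129,0.112807
H,1,1.5,0.1027,0.102506
H,1,2.0,0.08769,0.0874399
H,1,3.0,0.06921,0.0687595
H,1,5.0,0.05049,0.0495066
H,1,8.0,0.03746,0.0357768
H,1,10.0,0.03254,0.0304622
H,1,15.0,0.02539,0.0225304
C,6,0.015,0.8071,0.189212
C,6,0.02,0.442,0.18591
C,6,0.03,0.2562,0.179745
C,6,0.04,0.2076,0.174103
C,6,0.05,0.1871,0.168919
C,6,0.06,0.1753,0.16414
C,6,0.08,0.161,0.155616
C,6,0.1,0.1514,0.148234
C,6,0.15,0.1347,0.13345
C,6,0.2,0.1229,0.122283
C,6,0.3,0.1066,0.106329
C,6,0.4,0.09546,0.0952671
C,6,0.5,0.08715,0.0869903
C,6,0.6,0.08058,0.0804715
C,6,0.8,0.07076,0.0706832
C,6,1.0,0.06361,0.0635379
C,6,1.25,0.0569,0.0568028
C,6,1.5,0.05179,0.0516155
C,6,2.0,0.04442,0.0440294
C,6,3.0,0.03562,0.034623
C,6,5.0,0.02708,0.0249285
C,6,8.0,0.02154,0.018015
C,6,10.0,0.01959,0.0153389
C,6,15.0,0.01698,0.0113449
N,7,0.015,1.237,0.18929
N,7,0.02,0.6178,0.185987
N,7,0.03,0.3066,0.17982
N,7,0.04,0.2288,0.174175
N,7,0.05,0.198,0.168989
N,7,0.06,0.1817,0.164208
N,7,0.08,0.1639,0.15568
N,7,0.1,0.1529,0.148296
N,7,0.15,0.1353,0.133506
N,7,0.2,0.1233,0.122334
N,7,0.3,0.1068,0.106373
N,7,0.4,0.09557,0.0953068
N,7,0.5,0.08719,0.0870265
N,7,0.6,0.08063,0.0805051
N,7,0.8,0.07081,0.0707127
N,7,1.0,0.06364,0.0635644
N,7,1.25,0.05693,0.0568264
N,7,1.5,0.0518,0.051637
N,7,2.0,0.0445,0.0440477
N,7,3.0,0.03579,0.0346375
N,7,5.0,0.02742,0.0249389
N,7,8.0,0.02209,0.0180225
N,7,10.0,0.02024,0.0153453
N,7,15.0,0.01782,0.0113496
O,8,0.015,1.836,0.189397
O,8,0.02,0.8651,0.186092
O,8,0.03,0.3779,0.179921
O,8,0.04,0.2585,0.174273
O,8,0.05,0.2132,0.169084
O,8,0.06,0.1907,0.1643
O,8,0.08,0.1678,0.155768
O,8,0.1,0.1551,0.148379
O,8,0.15,0.1361,0.133581
O,8,0.2,0.1237,0.122402
O,8,0.3,0.107,0.106433
O,8,0.4,0.09566,0.0953604
O,8,0.5,0.08729,0.0870755
O,8,0.6,0.0807,0.0805503
O,8,0.8,0.07087,0.0707525
O,8,1.0,0.06372,0.0636002
O,8,1.25,0.05697,0.0568584
O,8,1.5,0.05185,0.0516661
O,8,2.0,0.04459,0.0440725
O,8,3.0,0.03597,0.0346569
O,8,5.0,0.02777,0.0249529
O,8,8.0,0.02263,0.0180326
O,8,10.0,0.02089,0.0153539
O,8,15.0,0.01866,0.011356
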