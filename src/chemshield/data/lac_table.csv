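# Published linear attenuation coefficients (1/cm) for compounds 2a-2f at five
# photon energies, as computed by three independent codes (XCOM, Phy-X, GATE).
compound,source,energy_keV,lac_cm1
2a,XCOM,80,0.2409
2a,XCOM,120,0.2409
2a,XCOM,662,0.1190
2a,XCOM,1173,0.0911
2a,XCOM,1332,0.0887
2a,Phy-X,80,0.2757
2a,Phy-X,120,0.2452
2a,Phy-X,662,0.1322
2a,Phy-X,1173,0.1007
2a,Phy-X,1332,0.0943
2a,GATE,80,0.2733
2a,GATE,120,0.2465
2a,GATE,662,0.1438
2a,GATE,1173,0.1011
2a,GATE,1332,0.0964
2b,XCOM,80,0.2684
2b,XCOM,120,0.2430
2b,XCOM,662,0.1334
2b,XCOM,1173,0.1016
2b,XCOM,1332,0.0948
2b,Phy-X,80,0.2774
2b,Phy-X,120,0.2468
2b,Phy-X,662,0.1330
2b,Phy-X,1173,0.1013
2b,Phy-X,1332,0.0949
2b,GATE,80,0.2779
2b,GATE,120,0.2493
2b,GATE,662,0.1382
2b,GATE,1173,0.1016
2b,GATE,1332,0.0950
2c,XCOM,80,0.2694
2c,XCOM,120,0.2445
2c,XCOM,662,0.1333
2c,XCOM,1173,0.1016
2c,XCOM,1332,0.0952
2c,Phy-X,80,0.2784
2c,Phy-X,120,0.2477
2c,Phy-X,662,0.1335
2c,Phy-X,1173,0.1017
2c,Phy-X,1332,0.0953
2c,GATE,80,0.2786
2c,GATE,120,0.2484
2c,GATE,662,0.1353
2c,GATE,1173,0.1083
2c,GATE,1332,0.0939
2d,XCOM,80,0.2711
2d,XCOM,120,0.2461
2d,XCOM,662,0.1341
2d,XCOM,1173,0.1023
2d,XCOM,1332,0.0959
2d,Phy-X,80,0.2802
2d,Phy-X,120,0.2493
2d,Phy-X,662,0.1344
2d,Phy-X,1173,0.1024
2d,Phy-X,1332,0.0959
2d,GATE,80,0.2817
2d,GATE,120,0.2512
2d,GATE,662,0.1344
2d,GATE,1173,0.1088
2d,GATE,1332,0.0976
2e,XCOM,80,0.2731
2e,XCOM,120,0.2479
2e,XCOM,662,0.1351
2e,XCOM,1173,0.1030
2e,XCOM,1332,0.0964
2e,Phy-X,80,0.2822
2e,Phy-X,120,0.2511
2e,Phy-X,662,0.1354
2e,Phy-X,1173,0.1031
2e,Phy-X,1332,0.0966
2e,GATE,80,0.2721
2e,GATE,120,0.2528
2e,GATE,662,0.1369
2e,GATE,1173,0.1030
2e,GATE,1332,0.0998
2f,XCOM,80,0.2921
2f,XCOM,120,0.2652
2f,XCOM,662,0.1445
2f,XCOM,1173,0.1103
2f,XCOM,1332,0.1032
2f,Phy-X,80,0.3017
2f,Phy-X,120,0.2685
2f,Phy-X,662,0.1448
2f,Phy-X,1173,0.1103
2f,Phy-X,1332,0.1033
2f,GATE,80,0.3027
2f,GATE,120,0.2918
2f,GATE,662,0.1531
2f,GATE,1173,0.1187
2f,GATE,1332,0.1072
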