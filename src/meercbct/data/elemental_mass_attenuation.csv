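element,energy_keV,mu_over_rho_cm2_g
H,10,0.3854
H,15,0.3764
H,20,0.3695
H,30,0.3570
H,40,0.3458
H,50,0.3355
H,60,0.3260
H,80,0.3091
H,100,0.2944
H,150,0.2651
C,10,2.373
C,15,0.8071
C,20,0.4420
C,30,0.2562
C,40,0.2076
C,50,0.1871
C,60,0.1753
C,80,0.1610
C,100,0.1514
C,150,0.1347
N,10,3.879
N,15,1.236
N,20,0.6178
N,30,0.3066
N,40,0.2288
N,50,0.1980
N,60,0.1817
N,80,0.1639
N,100,0.1529
N,150,0.1353
O,10,5.952
O,15,1.836
O,20,0.8651
O,30,0.3779
O,40,0.2585
O,50,0.2132
O,60,0.1907
O,80,0.1678
O,100,0.1551
O,150,0.1361
Al,10,26.23
Al,15,7.955
Al,20,3.441
Al,30,1.128
Al,40,0.5685
Al,50,0.3681
Al,60,0.2778
Al,80,0.2018
Al,100,0.1704
Al,150,0.1378
Cl,10,33.80
Cl,15,10.60
Cl,20,4.600
Cl,30,1.480
Cl,40,0.7000
Cl,50,0.4700
Cl,60,0.3700
Cl,80,0.2500
Cl,100,0.2100
Cl,150,0.1600
I,10,205.3
I,15,61.20
I,20,26.00
I,30,7.850
I,33.169,5.850
I,33.170,31.70
I,40,18.20
I,50,9.450
I,60,5.550
I,80,2.460
I,100,1.330
I,150,0.4800
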