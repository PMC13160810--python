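criterion,indicator,local_weight,combined_weight,rank
M,M1,0.1560,0.410,1
M,M2,0.1428,0.310,3
M,M3,0.1426,0.297,6
M,M4,0.0964,0.021,12
M,M5,0.0948,0.140,13
O,O1,0.2497,0.364,4
O,O2,0.1221,0.012,2
O,O3,0.2449,0.035,5
O,O4,0.1836,0.053,10
O,O5,0.2000,0.102,8
N,N1,0.2879,0.043,11
N,N2,0.2485,0.259,7
N,N3,0.1250,0.089,9
N,N4,0.1150,0.004,14
N,N5,0.2250,0.129,15
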