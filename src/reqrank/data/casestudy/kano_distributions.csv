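indicator_id,a_pct,o_pct,m_pct,i_pct,r_pct,q_pct,reported_category,reported_better_pct,reported_worse_pct
A1,11.45,31.23,54.32,3.54,2.78,4.98,M,64.89,-51.45
A2,11.34,32.16,37.31,20.78,9.34,1.78,M,23.74,-43.78
A3,14.12,39.11,45.36,11.43,2.51,4.88,M,62.93,-9.34
A4,7.23,42.21,6.43,22.76,13.46,1.17,O,56.23,-9.15
A5,45.27,0.33,7.61,19.89,2.57,0.42,A,68.53,-46.23
B1,15.70,0.00,0.00,39.67,31.40,13.22,M,34.23,0.00
B2,32.41,36.71,11.01,39.43,6.45,7.35,O,50.30,-67.23
B3,19.43,24.79,29.76,12.67,2.91,19.34,M,21.10,-23.45
B4,41.17,4.42,32.40,21.37,2.98,7.79,A,34.03,-4.22
C1,56.12,9.45,4.13,41.09,4.32,2.78,A,45.34,-10.35
C2,21.72,23.34,31.64,26.86,8.99,6.44,M,26.34,-34.12
C3,1.59,3.11,7.53,56.58,21.59,8.13,I,24.21,-2.00
C4,26.45,15.01,20.83,24.79,5.79,5.15,A,12.24,-45.75
C5,17.88,20.66,19.43,17.32,6.74,9.20,O,34.87,-45.78
D1,47.35,9.11,12.83,10.18,12.79,4.13,M,11.67,-34.45
D2,1.65,2.96,7.92,68.58,21.22,3.21,I,46.23,-4.01
D3,41.17,4.42,32.40,21.37,2.98,7.79,A,34.03,-4.22
D4,3.23,5.45,4.99,70.58,14.32,4.21,I,45.29,-2.70
D5,17.11,39.17,12.76,27.94,3.41,1.54,O,58.31,-6.78
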