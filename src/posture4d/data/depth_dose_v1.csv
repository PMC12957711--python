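# posture4d RBE-weighted depth-dose parameterization, version 1
# range ladder 3 mm; peak_value in GyRBE*mm^2/particle; lateral sigma model sqrt(sigma_air^2 + (sigma_growth*depth)^2)
energy_index,range_mm,sigma_prox_mm,sigma_distal_mm,entrance_frac,plateau_slope,peak_value,sigma_air_mm,sigma_growth
0,21.0,1.92,1.2,0.18,0.06,0.005,4.0,0.025
1,24.0,1.98,1.2,0.18,0.06,0.005,4.0,0.025
2,27.0,2.04,1.2,0.18,0.06,0.005,4.0,0.025
3,30.0,2.1,1.2,0.18,0.06,0.005,4.0,0.025
4,33.0,2.16,1.2,0.18,0.06,0.005,4.0,0.025
5,36.0,2.22,1.2,0.18,0.06,0.005,4.0,0.025
6,39.0,2.28,1.2,0.18,0.06,0.005,4.0,0.025
7,42.0,2.34,1.2,0.18,0.06,0.005,4.0,0.025
8,45.0,2.4,1.2,0.18,0.06,0.005,4.0,0.025
9,48.0,2.46,1.2,0.18,0.06,0.005,4.0,0.025
10,51.0,2.52,1.2,0.18,0.06,0.005,4.0,0.025
11,54.0,2.58,1.2,0.18,0.06,0.005,4.0,0.025
12,57.0,2.64,1.2,0.18,0.06,0.005,4.0,0.025
13,60.0,2.7,1.2,0.18,0.06,0.005,4.0,0.025
14,63.0,2.76,1.2,0.18,0.06,0.005,4.0,0.025
15,66.0,2.82,1.2,0.18,0.06,0.005,4.0,0.025
16,69.0,2.88,1.2,0.18,0.06,0.005,4.0,0.025
17,72.0,2.94,1.2,0.18,0.06,0.005,4.0,0.025
18,75.0,3.0,1.2,0.18,0.06,0.005,4.0,0.025
19,78.0,3.06,1.2,0.18,0.06,0.005,4.0,0.025
20,81.0,3.12,1.2,0.18,0.06,0.005,4.0,0.025
21,84.0,3.18,1.2,0.18,0.06,0.005,4.0,0.025
22,87.0,3.24,1.2,0.18,0.06,0.005,4.0,0.025
23,90.0,3.3,1.2,0.18,0.06,0.005,4.0,0.025
24,93.0,3.36,1.2,0.18,0.06,0.005,4.0,0.025
25,96.0,3.42,1.2,0.18,0.06,0.005,4.0,0.025
26,99.0,3.48,1.2,0.18,0.06,0.005,4.0,0.025
27,102.0,3.54,1.2,0.18,0.06,0.005,4.0,0.025
28,105.0,3.6,1.2,0.18,0.06,0.005,4.0,0.025
29,108.0,3.66,1.2,0.18,0.06,0.005,4.0,0.025
30,111.0,3.72,1.2,0.18,0.06,0.005,4.0,0.025
31,114.0,3.78,1.2,0.18,0.06,0.005,4.0,0.025
32,117.0,3.84,1.2,0.18,0.06,0.005,4.0,0.025
33,120.0,3.9,1.2,0.18,0.06,0.005,4.0,0.025
34,123.0,3.96,1.2,0.18,0.06,0.005,4.0,0.025
35,126.0,4.02,1.2,0.18,0.06,0.005,4.0,0.025
36,129.0,4.08,1.2,0.18,0.06,0.005,4.0,0.025
37,132.0,4.14,1.2,0.18,0.06,0.005,4.0,0.025
38,135.0,4.2,1.2,0.18,0.06,0.005,4.0,0.025
39,138.0,4.26,1.2,0.18,0.06,0.005,4.0,0.025
40,141.0,4.32,1.2,0.18,0.06,0.005,4.0,0.025
41,144.0,4.38,1.2,0.18,0.06,0.005,4.0,0.025
42,147.0,4.44,1.2,0.18,0.06,0.005,4.0,0.025
43,150.0,4.5,1.2,0.18,0.06,0.005,4.0,0.025
44,153.0,4.56,1.2,0.18,0.06,0.005,4.0,0.025
45,156.0,4.62,1.2,0.18,0.06,0.005,4.0,0.025
46,159.0,4.68,1.2,0.18,0.06,0.005,4.0,0.025
47,162.0,4.74,1.2,0.18,0.06,0.005,4.0,0.025
48,165.0,4.8,1.2,0.18,0.06,0.005,4.0,0.025
49,168.0,4.86,1.2,0.18,0.06,0.005,4.0,0.025
50,171.0,4.92,1.2,0.18,0.06,0.005,4.0,0.025
51,174.0,4.98,1.2,0.18,0.06,0.005,4.0,0.025
52,177.0,5.04,1.2,0.18,0.06,0.005,4.0,0.025
53,180.0,5.1,1.2,0.18,0.06,0.005,4.0,0.025
54,183.0,5.16,1.2,0.18,0.06,0.005,4.0,0.025
55,186.0,5.22,1.2,0.18,0.06,0.005,4.0,0.025
56,189.0,5.28,1.2,0.18,0.06,0.005,4.0,0.025
57,192.0,5.34,1.2,0.18,0.06,0.005,4.0,0.025
58,195.0,5.4,1.2,0.18,0.06,0.005,4.0,0.025
59,198.0,5.46,1.2,0.18,0.06,0.005,4.0,0.025
60,201.0,5.52,1.2,0.18,0.06,0.005,4.0,0.025
61,204.0,5.58,1.2,0.18,0.06,0.005,4.0,0.025
62,207.0,5.64,1.2,0.18,0.06,0.005,4.0,0.025
63,210.0,5.7,1.2,0.18,0.06,0.005,4.0,0.025
64,213.0,5.76,1.2,0.18,0.06,0.005,4.0,0.025
65,216.0,5.82,1.2,0.18,0.06,0.005,4.0,0.025
66,219.0,5.88,1.2,0.18,0.06,0.005,4.0,0.025
67,222.0,5.94,1.2,0.18,0.06,0.005,4.0,0.025
68,225.0,6.0,1.2,0.18,0.06,0.005,4.0,0.025
69,228.0,6.06,1.2,0.18,0.06,0.005,4.0,0.025
70,231.0,6.12,1.2,0.18,0.06,0.005,4.0,0.025
71,234.0,6.18,1.2,0.18,0.06,0.005,4.0,0.025
72,237.0,6.24,1.2,0.18,0.06,0.005,4.0,0.025
73,240.0,6.3,1.2,0.18,0.06,0.005,4.0,0.025
74,243.0,6.36,1.2,0.18,0.06,0.005,4.0,0.025
75,246.0,6.42,1.2,0.18,0.06,0.005,4.0,0.025
76,249.0,6.48,1.2,0.18,0.06,0.005,4.0,0.025
77,252.0,6.54,1.2,0.18,0.06,0.005,4.0,0.025
78,255.0,6.6,1.2,0.18,0.06,0.005,4.0,0.025
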