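trial,trial_type,z_firing,constant,interval_fear,total_fear,probability
1,danger,2.32,1,1.00,1.00,1
2,danger,0.51,1,1.00,1.00,1
3,danger,0.81,1,1.00,1.00,1
4,danger,1.56,1,1.00,1.00,1
5,danger,1.41,1,-1.00,0.73,1
6,danger,2.92,1,1.00,1.00,1
7,uncertainty_shock,0.81,1,1.00,1.00,0.375
8,uncertainty_shock,-0.40,1,-0.33,0.47,0.375
9,uncertainty_shock,0.21,1,1.00,0.64,0.375
10,uncertainty_shock,-0.70,1,1.00,0.67,0.375
11,uncertainty_shock,-0.85,1,1.00,1.00,0.375
12,uncertainty_shock,-0.70,1,-1.00,0.64,0.375
13,uncertainty_omission,-0.70,1,1.00,1.00,0.375
14,uncertainty_omission,-0.70,1,-1.00,0.40,0.375
15,uncertainty_omission,-0.70,1,0.00,0.23,0.375
16,uncertainty_omission,0.66,1,1.00,1.00,0.375
17,uncertainty_omission,0.21,1,1.00,1.00,0.375
18,uncertainty_omission,-0.70,1,1.00,0.71,0.375
19,uncertainty_omission,-1.00,1,1.00,0.43,0.375
20,uncertainty_omission,1.11,1,1.00,1.00,0.375
21,uncertainty_omission,-0.09,1,-0.60,0.56,0.375
22,uncertainty_omission,-0.85,1,1.00,1.00,0.375
23,safety,-0.70,1,-0.33,0.06,0
24,safety,-0.70,1,0.00,0.27,0
25,safety,-0.70,1,1.00,-0.04,0
26,safety,-0.40,1,1.00,0.14,0
27,safety,-0.70,1,1.00,0.54,0
28,safety,-0.70,1,-0.50,0.03,0
29,safety,0.21,1,1.00,0.47,0
30,safety,-0.85,1,1.00,1.00,0
31,safety,0.06,1,1.00,0.20,0
32,safety,-0.70,1,1.00,-0.14,0
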