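patient,clinic_t25fw_speed_m_s,max_home_speed_m_s,mean_home_speed_m_s
1,1.5,1.43,1.30
9,1.0,1.11,0.96
10,1.4,1.49,1.32
12,1.0,0.86,0.84
13,1.4,1.38,1.27
14,1.0,0.83,0.81
15,1.1,0.99,0.88
17,1.0,0.99,0.95
18,0.9,0.88,0.81
19,1.3,1.16,1.07
21,1.3,1.24,1.17
22,1.1,1.17,1.07
23,0.5,0.55,0.55
24,0.8,0.66,0.61
25,0.4,0.38,0.38
26,0.7,0.78,0.77
27,1.7,1.57,1.30
28,0.8,0.78,0.71
29,1.1,1.26,1.16
30,1.0,1.42,1.20
31,1.3,1.33,1.26
32,1.4,1.44,1.25
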