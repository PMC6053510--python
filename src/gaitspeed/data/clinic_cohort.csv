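patient,edss,t25fw_mean_time_s,printed_speed_m_s
1,2,5.0,1.5
2,2,6.9,1.1
3,5.5,10.1,0.8
4,1,6.0,1.3
5,5,10.2,0.8
6,2.5,6.2,1.2
7,3,6.7,1.1
8,2.5,7.5,1.0
9,3,7.9,1.0
10,2,5.3,1.5
11,6,9.8,0.8
12,1,9.0,0.9
13,2,5.6,1.4
14,1.5,8.7,0.9
15,4,6.7,1.1
16,3.5,7.3,1.0
17,4,7.5,1.0
18,6,8.4,0.9
19,2,6.1,1.3
20,1,4.8,1.6
21,2.5,6.0,1.3
22,1.5,6.8,1.1
23,6,14.1,0.6
24,6,9.7,0.8
25,6,18.3,0.4
26,6,10.5,0.7
27,1,4.4,1.7
28,5.5,9.3,0.8
29,5.5,7.1,1.1
30,1.5,7.5,1.0
31,1,5.7,1.3
32,1,5.5,1.4
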