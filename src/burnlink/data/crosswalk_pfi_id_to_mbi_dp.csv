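# method: irt
# anchor_metric: MBI-DP
# target: PFI-ID
# source: published reference crosswalk (item set 2)
raw,t,se_t,anchor_expected_raw
0,35.46,5.36,1.31
1,40.99,3.59,2.41
2,42.76,3.58,2.99
3,45.06,3.18,3.94
4,46.90,3.21,4.85
5,48.51,3.10,5.74
6,50.19,3.02,6.77
7,51.81,3.07,7.89
8,53.30,3.10,9.01
9,54.91,3.07,10.30
10,56.47,3.11,11.62
11,57.93,3.07,12.88
12,59.47,3.04,14.22
13,60.92,3.10,15.47
14,62.31,3.10,16.64
15,63.85,3.08,17.87
16,65.35,3.09,19.01
17,66.84,3.02,20.07
18,68.40,2.98,21.11
19,69.95,3.02,22.09
20,71.52,3.05,23.01
21,73.28,3.03,23.94
22,75.24,3.16,24.83
23,77.17,3.21,25.58
24,80.61,3.98,26.69
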