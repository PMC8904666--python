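# method: irt
# anchor_metric: MBI-EE
# target: PFI-WE
# source: published reference crosswalk (item set 1)
raw,t,se_t,anchor_expected_raw
0,30.15,4.93,2.57
1,34.96,3.79,5.86
2,38.09,3.52,8.89
3,40.74,3.39,12.06
4,43.10,3.33,15.24
5,45.34,3.32,18.54
6,47.59,3.32,22.09
7,49.81,3.30,25.73
8,51.98,3.29,29.29
9,54.13,3.30,32.65
10,56.33,3.31,35.80
11,58.55,3.31,38.72
12,60.77,3.32,41.43
13,63.11,3.38,44.04
14,65.71,3.49,46.41
15,68.75,3.75,48.41
16,73.18,4.70,50.36
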