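# method: irt
# anchor_metric: MBI-EE
# target: MZSIB
# source: published reference crosswalk (item set 3)
raw,t,se_t,anchor_expected_raw
1,35.44,6.26,6.27
2,44.75,5.35,17.64
3,52.37,5.05,29.92
4,60.09,5.60,40.62
5,69.49,6.30,48.80
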