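# measurement_id=measurement3
# raw_sum=7801
tooth_id,share_pct
37,8
36,14
35,10
34,5
33,5
32,4
31,4
41,2
42,12
43,7
44,6
45,8
46,9
47,6
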