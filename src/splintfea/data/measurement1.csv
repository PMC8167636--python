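# measurement_id=measurement1
# raw_sum=11873
tooth_id,share_pct
37,17
36,21
35,7
34,4
33,1
32,6
31,6
41,1
42,3
43,2
44,4
45,2
46,8
47,18
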