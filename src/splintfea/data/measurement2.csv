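# measurement_id=measurement2
# raw_sum=5643
tooth_id,share_pct
37,5
36,35
35,13
34,9
33,5
32,1
31,1
41,1
42,4
43,4
44,3
45,2
46,12
47,5
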