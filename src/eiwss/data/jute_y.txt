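71.46
419.02
284.64
585.57
456.60
113.85
187.85
688.16
662.66
45.58
578.62
756.70
594.29
166.49
99.72
707.36
765.14
187.13
145.96
350.70
547.44
116.99
375.81
581.60
119.86
48.01
200.16
36.75
244.53
83.55
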