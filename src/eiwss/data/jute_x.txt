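693.73
704.66
323.83
778.17
123.06
637.66
383.43
151.48
108.94
50.16
671.49
183.16
257.44
727.23
291.27
101.15
376.42
163.40
141.38
700.74
262.90
353.24
422.11
43.93
590.48
212.13
303.90
506.60
530.55
177.25
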