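size_bp
35
50
75
100
139
150
160
200
250
300
340
350
400
450
490
500
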