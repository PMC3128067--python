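# 50mer k=2 weight=17 span<=22 N=50 p=0.85 sensitivity=0.6571
1111*111*11111**1*1111
11111*1*11**1111111*11
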