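# 70mer k=2 weight=14 span<=21 N=70 p=0.85 sensitivity=0.9540
11*11**11111**1*1*111
1111*1*1***11*11*1111
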