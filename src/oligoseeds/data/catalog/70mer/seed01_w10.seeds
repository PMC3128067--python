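# 70mer k=1 weight=10 span<=17 N=70 p=0.85 sensitivity=0.9941
11*11**1*1*1**111
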