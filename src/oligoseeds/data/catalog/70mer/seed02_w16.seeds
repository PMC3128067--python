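# 70mer k=2 weight=16 span<=22 N=70 p=0.85 sensitivity=0.8778
11111*111**1111*1*1*11
111*1*11*11**1*1111111
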