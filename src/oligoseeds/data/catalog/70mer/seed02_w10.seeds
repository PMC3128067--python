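# 70mer k=2 weight=10 span<=17 N=70 p=0.85 sensitivity=0.9989
1*11*1**11***1111
111*1*1**1*11**11
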