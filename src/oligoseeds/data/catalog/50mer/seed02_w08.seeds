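# 50mer k=2 weight=8 span<=15 N=50 p=0.85 sensitivity=0.9991
11***1*11*1**11
1*11**1***111*1
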