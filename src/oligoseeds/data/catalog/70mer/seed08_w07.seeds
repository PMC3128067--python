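# 70mer k=8 weight=7 span<=14 N=70 p=0.85 sensitivity=1.0000
1*11******1111
1*1**11**1**11
1*1*11***1*1*1
111*1*1***1**1
11*1*1**1**1*1
11****1*11**11
11**1**1***111
1*11***11***11
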