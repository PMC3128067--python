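# 50mer k=16 weight=11 span<=18 N=50 p=0.85 sensitivity=0.9988
111**11*1*1*1*1*11
111*1****11*1*1111
11**111*1**1*111*1
1111*1*11*1***11*1
1*1*1*111**1**1111
11*1***1111*1*1*11
11111***1**111**11
1*11*11*11****1111
11*11*1**111**1*11
11*11**11*1**1*111
11*1*111***11**111
1111*1*1***1*11*11
111**1***11*11*111
111**1*1*1*1**1111
1*111**1*11**111*1
11*1111**1**11**11
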