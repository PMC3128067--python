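# 50mer k=16 weight=8 span<=15 N=50 p=0.85 sensitivity=1.0000
1*11****11*1*11
111*****1*111*1
11*1*1*1*1**1*1
11*1****1*1*111
1*1111*****11*1
11*1**1**1*1*11
1*11***1**11*11
11**1*1***11*11
11***1*11**1*11
111***11****111
1*11*11***1**11
11**11***11**11
11**111*1***1*1
1*1*1**111**1*1
1*1*1*1**1**111
11**1**111***11
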