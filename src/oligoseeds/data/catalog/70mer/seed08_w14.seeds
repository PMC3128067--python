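# 70mer k=8 weight=14 span<=21 N=70 p=0.85 sensitivity=0.9925
11*111****11*11*11111
111**1**11*1111*1*111
11*11*111*1*1*11**111
1*1*1111**1*111*11*11
1111*1*11***1**111111
11111**111*11*1**1*11
1111*11**11***111*111
111*1*11*1111***1*111
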