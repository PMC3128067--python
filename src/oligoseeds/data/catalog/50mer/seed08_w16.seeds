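# 50mer k=8 weight=16 span<=22 N=50 p=0.85 sensitivity=0.8825
1111*1**1111*11*11*111
111111*11**1111*1*1*11
11*11*1*1*11*1111*1111
1111*111111*1**1**1111
111*1111*11**11*111*11
11111**11*1*1*1*111111
11*1*111*1*111111**111
111*111***111**1111111
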