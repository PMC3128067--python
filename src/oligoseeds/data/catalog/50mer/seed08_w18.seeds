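# 50mer k=8 weight=18 span<=22 N=50 p=0.85 sensitivity=0.7481
1111*1111*1111*11*1111
1111*11**111*111111111
11*11111111*1111*1*111
11111*1*11111111**1111
1111111111**1*111*1111
111*1111*1*111*1111111
111111*11*11*11*111111
11111**111111*11111*11
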