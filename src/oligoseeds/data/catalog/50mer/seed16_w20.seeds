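# 50mer k=16 weight=20 span<=22 N=50 p=0.85 sensitivity=0.6016
11111111111111**111111
111111111*111*11111111
1111*11111111111*11111
111*11111111*111111111
1111111111**1111111111
11111*11*1111111111111
1111111*11*11111111111
111*11111*111111111111
11111*1111111111*11111
1111*1*111111111111111
111111111111111*1*1111
11111111*11111111*1111
111111111111*11111*111
1111111111111*1111*111
1111111*111111*1111111
111111*1111*1111111111
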