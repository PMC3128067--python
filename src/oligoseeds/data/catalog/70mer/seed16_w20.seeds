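# 70mer k=16 weight=20 span<=22 N=70 p=0.85 sensitivity=0.7659
1111*11*11111111111111
11111111*1111111*11111
11111*11111111111*1111
111111*111*11111111111
11111111111*111111*111
11111*1*11111111111111
11111111*111111*111111
111*11111111*111111111
111111111*1111*1111111
1111111111*11111*11111
111111111*11*111111111
111111*11111111*111111
1111111111111*111*1111
11111111111*1*11111111
1111*111111111111*1111
111*1111111111*1111111
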