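# 50mer k=4 weight=20 span<=22 N=50 p=0.85 sensitivity=0.4794
11111111111111*1*11111
1111*111*1111111111111
1111111111*1111111*111
111111*11111*111111111
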