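# 70mer k=2 weight=20 span<=22 N=70 p=0.85 sensitivity=0.5738
1111*11111111111*11111
11111111*111*111111111
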