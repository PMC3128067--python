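# 70mer k=2 weight=19 span<=22 N=70 p=0.85 sensitivity=0.6632
11111111111*111*1*1111
11111*11*1111*11111111
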