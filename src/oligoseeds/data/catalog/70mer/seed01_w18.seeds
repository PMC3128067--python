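# 70mer k=1 weight=18 span<=22 N=70 p=0.85 sensitivity=0.6478
1111*111*11*1111*11111
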