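# 50mer k=1 weight=13 span<=20 N=50 p=0.85 sensitivity=0.8318
1111*1**11**11*1*111
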