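# 70mer k=2 weight=13 span<=20 N=70 p=0.85 sensitivity=0.9755
11*11*1*1*1111***111
1111*11**1*1**11*111
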