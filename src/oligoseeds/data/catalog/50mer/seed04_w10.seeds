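# 50mer k=4 weight=10 span<=17 N=50 p=0.85 sensitivity=0.9967
11*1**1*11***1111
1111***11**11*1*1
11**11**1*1*11*11
11111*1***1*1**11
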