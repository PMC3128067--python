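# 70mer k=4 weight=8 span<=15 N=70 p=0.85 sensitivity=1.0000
1**1*111***11*1
11**1*11***1*11
111***1*1*11**1
111*1****1**111
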