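# 50mer k=2 weight=13 span<=20 N=50 p=0.85 sensitivity=0.9079
111*1*1***1111*11*11
111*11*111**1**1*111
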