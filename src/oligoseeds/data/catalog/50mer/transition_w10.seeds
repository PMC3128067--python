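# 50mer transition weight=10+2@ span<=17 N=50 p=0.85 sensitivity~=0.9318
11@11*@1*1*1**111
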