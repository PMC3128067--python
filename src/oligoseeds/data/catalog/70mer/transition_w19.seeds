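# 70mer transition weight=19+2@ span<=22 N=70 p=0.85 sensitivity~=0.4791
11111@1111*111@1111111
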