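# 50mer transition weight=13+2@ span<=20 N=50 p=0.85 sensitivity~=0.7624
111@1*11**11@*1*1111
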