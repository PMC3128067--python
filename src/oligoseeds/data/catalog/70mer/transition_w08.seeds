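# 70mer transition weight=8+2@ span<=15 N=70 p=0.85 sensitivity~=0.9985
111@*1*1@*1**11
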