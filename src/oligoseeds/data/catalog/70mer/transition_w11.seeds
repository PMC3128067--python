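# 70mer transition weight=11+2@ span<=18 N=70 p=0.85 sensitivity~=0.9663
111**1*11@*1@1*111
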