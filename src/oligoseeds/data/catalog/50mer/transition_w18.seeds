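# 50mer transition weight=18+2@ span<=22 N=50 p=0.85 sensitivity~=0.4031
11111*1111@11*111@1111
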