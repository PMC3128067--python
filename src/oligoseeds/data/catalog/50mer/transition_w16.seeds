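# 50mer transition weight=16+2@ span<=22 N=50 p=0.85 sensitivity~=0.5470
111*111@1*@111*11*1111
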