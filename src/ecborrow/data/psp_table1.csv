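study,n,mean,se
Boxer,153,10.9,0.99
Tolosa,31,11.4,1.13
Hoglinger,59,10.5,1.00
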