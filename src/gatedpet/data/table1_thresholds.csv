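patient,gated_suv,nongated_suv
1,4.3,3.8
2,4.6,4.0
3,5.0,5.0
4,4.9,3.7
5,4.1,3.0
6,4.3,3.4
7,4.8,3.8
8,3.9,3.7
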