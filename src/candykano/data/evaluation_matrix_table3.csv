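forward,reverse_1,reverse_2,reverse_3,reverse_4,reverse_5
1,Q,R,R,R,R
2,M,I,I,I,R
3,M,I,I,I,R
4,M,I,I,I,R
5,O,A,A,A,Q
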