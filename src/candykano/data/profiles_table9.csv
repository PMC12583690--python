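code,importance,beta_pos,beta_neg,label_ratio,label_candy,label_normal,label_bw
A1,4.2838,0.0225,0.0231,O,M,O,O
A2,4.1811,0.0221,0.0224,O,O,I,O
A3,3.6973,0.0203,0.0202,I,I,I,I
A4,4.3919,0.0227,0.0238,O,M,O,O
A5,4.5946,0.0234,0.0249,O,C,O,O
A6,4.6541,0.0232,0.0246,O,C,O,O
A7,3.2730,0.0182,0.0186,I,I,I,I
A8,4.2324,0.0222,0.0226,O,O,I,O
A9,3.7946,0.0206,0.0210,I,O,I,I
A10,4.2162,0.0223,0.0221,O,O,I,A
A11,3.0027,0.0179,0.0182,I,I,I,I
B1,4.6405,0.0236,0.0247,O,C,O,O
B2,4.2135,0.0225,0.0223,O,O,I,O
B3,3.8297,0.0218,0.0214,A,O,I,I
B4,3.5703,0.0217,0.0210,I,O,I,I
B5,4.2000,0.0226,0.0239,O,M,O,O
B6,4.0622,0.0218,0.0221,O,O,I,M
C1,4.1000,0.0216,0.0211,I,O,I,I
C2,3.6054,0.0201,0.0200,I,I,I,I
C3,4.6081,0.0232,0.0246,O,C,O,O
C4,4.2054,0.0217,0.0223,M,O,I,M
C5,3.6676,0.0213,0.0204,I,A,I,I
C6,3.7811,0.0212,0.0222,M,O,I,I
C7,4.3405,0.0229,0.0236,O,M,I,I
C8,4.0027,0.0213,0.0217,I,O,I,I
C9,4.0973,0.0221,0.0226,O,O,I,O
C10,3.9568,0.0220,0.0213,A,O,I,A
C11,3.9649,0.0214,0.0218,M,O,I,I
D1,3.9432,0.0225,0.0209,A,O,I,A
D2,4.4676,0.0229,0.0225,O,A,O,O
D3,4.1189,0.0223,0.0226,O,O,O,O
D4,4.6541,0.0234,0.0237,O,C,O,O
D5,4.4486,0.0225,0.0230,O,M,O,O
D6,4.1270,0.0218,0.0217,A,O,I,M
D7,4.3892,0.0222,0.0231,O,M,O,O
D8,4.2703,0.0217,0.0226,M,O,I,M
D9,4.3865,0.0226,0.0230,O,M,O,O
D10,4.2459,0.0218,0.0224,O,O,I,M
E1,4.3757,0.0226,0.0207,A,O,I,O
E2,4.1351,0.0218,0.0204,A,A,I,I
E3,3.3919,0.0197,0.0179,I,I,I,I
E4,3.5784,0.0199,0.0184,I,I,I,I
E5,3.8595,0.0211,0.0194,I,A,I,I
E6,3.8297,0.0204,0.0196,I,I,I,I
E7,3.9622,0.0214,0.0202,I,A,I,I
E8,3.9514,0.0213,0.0196,I,A,I,I
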