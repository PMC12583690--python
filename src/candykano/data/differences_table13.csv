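code,perspective_child,perspective_old,income_low,income_high,relationship_bad,relationship_good,distance_far,distance_near,selfcare_poor,selfcare_good
A1,M,A,M,M,M,M,M,O,M,M
A2,O,O,O,O,O,O,O,O,O,O
A3,I,I,I,A,I,I,I,I,I,A
A4,M,M,M,M,M,M,M,M,M,M
A5,C,C,C,C,C,C,C,C,C,C
A6,M,C,C,C,C,C,C,C,C,C
A7,I,I,I,I,I,I,I,I,I,I
A8,O,O,O,O,O,O,O,O,O,O
A9,O,M,O,O,O,M,O,M,M,O
A10,O,O,O,O,O,O,O,O,O,O
A11,I,I,I,I,I,I,I,I,I,I
B1,C,C,C,C,C,C,C,C,C,C
B2,O,O,O,A,O,O,O,O,O,O
B3,O,O,O,O,O,O,O,O,O,O
B4,O,O,O,O,A,O,O,O,O,O
B5,M,M,M,M,M,M,M,C,M,M
B6,O,O,O,O,O,O,O,O,O,O
C1,O,O,O,O,O,O,O,O,O,O
C2,I,I,I,I,I,I,I,I,I,I
C3,C,C,C,C,C,C,C,M,C,C
C4,O,O,O,O,O,O,O,O,O,O
C5,O,A,A,O,A,O,O,A,A,A
C6,O,O,O,O,O,O,O,O,O,O
C7,C,M,C,M,C,M,C,M,C,M
C8,O,O,O,O,O,O,O,O,O,O
C9,O,O,O,O,O,O,O,M,O,O
C10,O,O,O,O,O,O,O,O,O,O
C11,O,O,O,O,O,O,O,O,O,O
D1,O,O,O,O,O,O,O,O,O,O
D2,O,O,A,O,C,O,O,A,A,O
D3,O,O,O,O,M,O,O,O,O,O
D4,C,C,C,C,C,C,C,C,C,C
D5,O,M,M,M,M,O,M,O,M,O
D6,O,O,O,O,O,O,O,O,O,O
D7,M,M,M,M,M,M,M,O,M,M
D8,O,O,O,O,O,O,O,O,O,O
D9,M,M,M,O,C,M,O,M,M,O
D10,O,O,O,O,O,O,O,O,O,O
E1,O,O,O,O,O,A,A,O,O,O
E2,A,A,A,O,O,A,A,O,O,A
E3,I,I,I,I,I,I,I,I,I,I
E4,I,I,I,I,I,I,I,I,I,I
E5,A,A,A,A,A,A,A,A,A,A
E6,I,I,I,I,A,I,I,A,A,I
E7,A,A,A,A,A,A,A,O,A,A
E8,A,A,A,A,A,A,A,A,A,A
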