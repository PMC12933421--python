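condition,evacuated,not_evacuated
C1,2,220
F1,2,220
F2,2,220
F3,2,220
E1,3,219
E2,3,219
E3,2,220
T1,2,220
T2,2,220
T3,2,220
M1,26,196
M2,44,178
M3,12,210
FEN1,28,194
FEN2,48,174
FEN3,26,194
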