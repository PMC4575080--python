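>BEX3_standin_synthetic | SYNTHETIC composition-matched stand-in for mouse BEX3 (UniProt Q9WTZ9, not redistributed here); 124 aa, 6 Pro, 13 Glu (7 in the 55-120 protease-resistant core), 25 F/I/L/V/W/M hydrophobics (17 in the core), Leu-rich 78-102 segment with L94/L97/L99, C-terminal CLMP CaaX box, 2 Trp. NOT the real sequence.
MSEGKNNQRDTAHPSGVKNEQRDTLAHESGKNPQRDFTAEHWSGKENPQIREPDTSAEWH
SVGLKKNQRIDTVAHPSGELKNLVQEIRDLMTELFALHLSEGKNLQRDTLAEHSGKNEQR
CLMP
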