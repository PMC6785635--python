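position	residue_number
Pos1	41
Pos2	44
Pos3	45
Pos12	82
Pos16	164
Pos18	168
Pos28	353
Pos31	359
Pos37	469
Pos40	477
Pos43	483
Pos46	503
Pos47	504
Pos50	511
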