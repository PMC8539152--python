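atom_type	neighbors	meaning	threshold_low	threshold_high	unit
H	H Acceptor	intramolecular H bridge: acidic H (on O, N or S) to non-bonded O/N/F acceptor	0	1.75	angstrom
H	.H	intramolecular H-H contact	0	2.0	angstrom
H	..H	intramolecular H-H contact	2.0	2.3	angstrom
Angle60		ring bond angle	0	74	degree
Angle90		ring bond angle	74	98	degree
Angle102		ring bond angle	98	106	degree
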