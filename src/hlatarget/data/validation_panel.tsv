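protein	peptide	pearson_r	rt_endogenous_min	rt_synthetic_min
IL13Ra	IVDPGYLGY	0.9235	73.9	75.8
PRAME	SLLQHLIGL	0.9728	74.9	75.8
MAGEA1	KVLEYVIKV	0.9569	50.6	52.7
MAGEC1	FAFGEPREL	0.9874	54.2	54.1
MAGED1	KEIDKEEHL	0.9849	21.4	19.9
MAGED2	NADPQAVTM	0.9775	26.6	28.8
MAGED2	DVYPEIIER	0.9742	52.5	55.6
MAGED2	YSLEKVFGI	0.5359	68.2	57.4
MAGED2	KEIDKNDHLYIL	0.9607	43.0	46.8
MAGEF1	FLFGYPKRL	0.9564	55.8	58.9
MAGEF1	ILFPDIIARA	0.9936	71.8	70.1
MAGED4	MNIGDEALIGR	0.9828	44.3	46.1
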