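# Case-study date table: Early Bronze Age Lech Valley pedigrees.
# c14_age/err: conventional radiocarbon age BP and 1-sigma error.
# hbco: human bone collagen offset in years (subtract from c14_age before modelling).
# POST_44's placement is ambiguous (1st or 2nd generation); the pedigree fixture
# files carry both variants, this table stores the uncle variant (level 2).
site	feature	id	generation_level	c14_age	err	aad_min	aad_max	hbco
POST	44	POST_44	2	3681	23	30	45	15
POST	50	POST_50	3	3707	24	30	35	15
POST	35	POST_35	3	3621	20	35	55	20
POST	140	POST_140	4	3631	20	25	55	10
POST	137	POST_137	5	3608	20	9	15	0
POST	131	POST_131	5	3635	20	6	10	0
POST	28	POST_28	5	3608	20	17	25	5
POST	47	POST_47	5	3662	24	20	30	5
OBKR	6	OBKR_6	1	3611	23	15	18	0
OBKR	80	OBKR_80	2	3664	24	30	40	15
OBKR	86	OBKR_86	2	3615	24	30	40	15
OBKR	81	OBKR_81	4	3602	24	4	4	0
OBKR	82	OBKR_82	4	3600	24	3	3	0
AITI	87	AITI_87	1	3433	28	30	40	15
AITI	86	AITI_86	2	3480	34	4	6	0
AITI	119	AITI_119	2	3470	27	13	17	0
AITI	120	AITI_120	2	3417	27	30	30	10
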