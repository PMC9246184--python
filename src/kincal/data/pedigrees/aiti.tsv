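# AITI nuclear family: mother AITI_87 with three sons.
AITI_87	1	30	40
AITI_86	2	4	6
AITI_119	2	13	17
AITI_120	2	30	30
[edges]
AITI_87	AITI_86
AITI_87	AITI_119
AITI_87	AITI_120
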