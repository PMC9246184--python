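# OBKR pedigree: four generations with the 3rd undated (no radiocarbon date);
# sequencing models collapse levels 1,2,4 to three phases.
OBKR_6	1	15	18
OBKR_80	2	30	40
OBKR_86	2	30	40
OBKR_81	4	4	4
OBKR_82	4	3	3
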