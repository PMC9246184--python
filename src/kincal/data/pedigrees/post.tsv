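# POST pedigree, uncle variant: POST_44 placed as uncle of POST_50 (2nd level).
# Right-strand adult models use the subset {POST_44, POST_50, POST_35,
# POST_140, POST_28, POST_47}.  Parent-child edges beyond the published
# mother-son pair are not printed in the source material and are omitted.
POST_44	2	30	45
POST_50	3	30	35
POST_35	3	35	55
POST_140	4	25	55
POST_137	5	9	15
POST_131	5	6	10
POST_28	5	17	25
POST_47	5	20	30
[edges]
POST_35	POST_140
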