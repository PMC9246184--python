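# POST pedigree, grandfather variant: POST_44 in the 1st level, with the
# 2nd level undated (missing generation between POST_44 and POST_50/POST_35);
# model builders collapse the gap and may attach an interval prior for it.
POST_44	1	30	45
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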