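motif_len	r4	r5	r6	r7	r8	r9	r10	r_gt10
2	0	0	2169	1530	999	631	414	916
3	0	1868	786	408	226	118	67	162
4	990	255	116	57	22	7	1	7
5	358	116	40	15	1	1	1	0
6	442	187	68	34	15	5	6	6
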