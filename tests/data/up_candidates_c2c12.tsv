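miRNA	fold_change	p_value	n_sites
mmu-miR-133b	73.53	0.0001	1
mmu-miR-133a-1	68.49	0.0001	1
mmu-miR-206	40.16	0.0001	1
mmu-miR-1-2	11.78	0.0004	1
mmu-miR-196a-2	9.25	0.0006	5
mmu-miR-192	9.44	0.0007	6
mmu-miR-322	7.26	0.0001	20
mmu-miR-24-2	5.59	0.0001	21
mmu-miR-409	7.03	0.0001	4
mmu-miR-221	7.05	0.0001	33
mmu-miR-30e	4.31	0.01	4
mmu-miR-320	3.65	0.01	7
mmu-miR-9-3	3.52	0.01	21
mmu-miR-351	3.29	0.02	14
mmu-miR-199a-1	3.11	0.02	8
mmu-miR-380	3.04	0.02	4
mmu-miR-425	3.07	0.02	7
mmu-miR-130b	3.04	0.02	3
mmu-miR-145	3.03	0.03	12
mmu-miR-214	2.88	0.03	28
mmu-miR-138-2	2.86	0.03	1
mmu-miR-30a	2.66	0.03	3
mmu-miR-126	2.75	0.04	1
mmu-miR-200b	2.73	0.04	1
mmu-miR-15a	2.69	0.04	4
mmu-miR-153	2.71	0.04	1
mmu-miR-381	2.73	0.04	4
mmu-miR-130a	2.71	0.04	23
mmu-miR-154	2.69	0.04	4
mmu-miR-451	2.34	0.05	1
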