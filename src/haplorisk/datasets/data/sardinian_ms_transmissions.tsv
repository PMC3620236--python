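# Stratified X/Y-parent transmissions to affected offspring, by carriage of
# the *03:01-*02:01 risk haplotype (risk-positive: 269 informative parents
# from 269 patients; risk-negative: 634 informative parents from 422 patients).
#risk	*03:01-*02:01
label	t_pos	nt_pos	t_neg	nt_neg
*14:01-4-*05:031	3	8	23	26
*16:01-*05:02	30	61	101	148
*10:01-*05:01	10	8	15	24
*04:05-*03:01	35	12	55	22
*12:01-*03:01	5	5	13	17
*15:02-*06:01	0	10	5	16
*13:03-*03:01	17	2	17	6
*16:02-*05:02	2	2	1	4
*03:01-*03:01	0	0	1	2
*15:01-*06:02	14	6	18	10
*01	23	35	66	79
*04	43	36	100	74
*07	10	17	57	58
*08	9	1	14	8
*11	55	50	110	116
*13	8	14	29	14
*15	5	2	9	10
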