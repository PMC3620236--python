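#totals	2555	1365
label	case_count	control_count
*03:01-*02:01/*13:03-*03:01	40	5
*03:01-*02:01/*15:01-*06:02	50	7
*03:01-*02:01/*03:01-*02:01	339	65
*03:01-*02:01/*04:05-*03:01	96	19
*04:05-*03:01/*11	54	12
*03:01-*02:01/*08	28	8
*16:01-*05:02/*04:05-*03:01	51	15
*03:01-*02:01/*04	180	70
*03:01-*02:01/*11	212	91
*16:01-*05:02/*04	99	48
*03:01-*02:01/*01	104	52
*01/*11	64	33
*01/*04	53	33
*04/*07	36	21
*04/*11	63	41
*16:01-*05:02/*13	20	14
*03:01-*02:01/*16:01-*05:02	153	122
*04/*04	22	20
*16:01-*05:02/*11	88	83
*16:01-*05:02/*01	44	42
*04:05-*03:01/*04	16	15
*16:01-*05:02/*07	28	25
*11/*11	37	37
*03:01-*02:01/*07	35	35
*03:01-*02:01/*14:01-4-*05:031	16	22
*07/*11	15	22
*16:01-*05:02/*16:01-*05:02	24	47
*14:01-4-*05:031/*16:01-*05:02	7	19
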