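#totals	5110	2730
label	case_count	control_count
*13:03-*03:01	97	16
*04:05-*03:01	306	82
*15:01-*06:02	114	31
*08	71	21
*03:01-*02:01	1680	607
*04	576	312
*13	114	69
*11	656	420
*01	366	238
*07	197	143
*12:01-*03:01	56	44
*10:01-*05:01	80	68
*16:01-*05:02	603	513
*14:01-4-*05:031	77	77
*15:02-*06:01	45	54
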