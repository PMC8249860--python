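sample_id	group	n_neoantigens	n_nonsynonymous	hla_a	hla_b	hla_c	strategy
CIN1-1	CIN1	0	3	/	/	/	WES
CIN1-2	CIN1	1	3	–	40:01	12:03	WES
CIN1-3	CIN1	1	1	–	–	07:02	WES
CIN1-4	CIN1	3	3	26:01	–	07:02	WES
CIN1-5	CIN1	0	7	/	/	/	WES
CIN1-6	CIN1	1	3	11:01	–	–	WES
CIN1-8	CIN1	2	2	–	07:02/67:01	–	WES
CIN1-9	CIN1	2	1	26:01	–	–	WES
CIN1-10	CIN1	0	1	/	/	/	WES
CIN1-11	CIN1	2	1	26:01	67:01	–	WES
CIN2-1	CIN2	0	2	/	/	/	WES
CIN2-2	CIN2	3	3	–	37:01	–	WES
CIN2-3	CIN2	12	6	03:01	07:03	14:02	WES
CIN2-4	CIN2	10	3	26:01	40:01	07:02	WES
CIN2-5	CIN2	7	5	03:01/03:02	–	07:02	WES
CIN2-6	CIN2	2	1	03:02	–	–	WES
CIN2-7	CIN2	1	3	24:02	–	–	WES
CIN2-8	CIN2	2	2	–	40:01	–	WES
CIN2-10	CIN2	0	3	/	/	/	WES
CIN3-1	CIN3	61	16	02:01/11:01	07:03	12:03	WES
CIN3-3	CIN3	0	2	/	/	/	WES
CIN3-4	CIN3	10	1	23:01	15:01	07:02/12:03	WES
CIN3-5	CIN3	6	2	26:01	15:18/37:01	12:02	WES
CIN3-6	CIN3	3	2	–	55:02	–	WES
CIN3-7	CIN3	0	0	/	/	/	WES
T1	CC	392	241	26:01	15:18/67:*	12:*	WES
T2	CC	209	199	26:01	15:18	12:03	WES
T3	CC	36	26	26:01	15:18/55:02	12:03	WES
T4	CC	29	54	26:01	40:01	07:02	WES
T5	CC	732	800	34:01	15:18/67:01	07:02	WES
T6	CC	589	504	03:01	40:01	07:02	WES
T7	CC	64	33	11:01	37:01	12:03	WES
T8	CC	12	15	01:02	40:01	07:02	WES
T9	CC	20	61	26:01	15:18	07:02	WES
T10	CC	42	71	26:01	07:02	07:02	WES
CC-H024	CC	155	77	02:07/02:01	35:01	03:03	WES/RNA-seq
CC-H027	CC	5	40	02:07	52:01	01:02	WES/RNA-seq
CC-X004	CC	134	129	02:01	52:01	01:02	WES/RNA-seq
CC-X008	CC	38	28	31:02	40:06	03:04/14:02	WES/RNA-seq
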