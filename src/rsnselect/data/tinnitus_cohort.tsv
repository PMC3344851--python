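id	sex	age_years	ear	duration_years	frequency_hz	thi	tq	loudness_0_10
P01	F	44	Right	9	8000	58	35	7
P02	M	47	Right	33	3000	38	22	10
P03	M	36	Left	1.75	2500	84	58	6.5
P04	M	66	Left	2	4000	80	56	8
P05	M	67	Left	3.75	1500	30	26	5
P06	M	57	Bilateral	2	8000	50	52	6.5
P07	M	50	Right	10	6000	38	29	3
P08	F	60	Bilateral	>20	4000	20	20	3
P09	F	42	Right	2.4	3000	40	34	2.5
P10	M	33	Left	3.5	8000	32	22	4
P11	F	60	Bilateral	5	3000	36	21	4.5
P12	F	66	Left	2	6000	16	18	4
P13	F	52	Left	5	6000	44	22	5
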