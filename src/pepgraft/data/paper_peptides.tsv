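name	sequence	mw	kd_uM	kd_sd_uM	purity_pct	a121_position	anchor_positions	group	experimental
Ar5Y_1	FNWDYSWKSERLKEAYDL	2350.59	3.39	0.85	96.66	3		five_anchor	yes
Ar5Y_2	FNWDYSLEELREKAKYK	2219.50	3.14	0.92	95.80	3		five_anchor	yes
Ar5Y_3	TEKDYRHGNIRMKLAYDL	2223.56	3.13	0.45	96.71	3		five_anchor	yes
Ar5Y_4	GNWDYNSQRAQLYNQ	1856.94	1.38	0.39	98.24	3	3;4;5;9;13	five_anchor	yes
W3A	GNADYNSQRAQLYNQ	1741.81	8.08	0.08	97.56	3		ala_mutant	yes
D4A	GNWAYNSQRAQLYNQ	1812.93	18.94	1.10	95.18	3		ala_mutant	yes
Y5A	GNWDANSQRAQLYNQ	1764.85	20.15	0.98	96.76	3		ala_mutant	yes
R9A	GNWDYNSQAAQLYNQ	1771.83	21.20	1.56	96.65	3		ala_mutant	yes
Y13A	GNWDYNSQRAQLANQ	1765.85	10.23	1.35	98.91	3		ala_mutant	yes
Ar3_ref	ADYK	495.54	370.40	2.92	95.17	1		three_anchor	yes
Ar3_1	WDYD	597.59	22.35	0.34	98.40	1		three_anchor	yes
Ar4_1	GIDYEERWK	1195.31	28.28	0.91	95.14	2		four_anchor	yes
Ar4_2	LDYDGRLSQ	1066.14	83.90	1.90	96.46	1		four_anchor	yes
Ar5M_1	LDYGDKREGQMAE	1511.64	21.60	1.03	98.81	1		five_anchor_met	yes
Ar5M_2	LDYVNRRKMYQ	1485.74	3.32	0.67	96.08	1		five_anchor_met	yes
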