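gene	genome_position	edited_nucleotide	amino_acid_change	editing_type	position_in_codon
matK	2313	C1234	H412→Y412	C→T	1
matK	2846	C701	S234→F234	C→T	2
matK	3102	C445	H149→Y149	C→T	1
atpA	11605	C914	S305→L305	C→T	2
atpA	11728	C791	P264→L264	C→T	2
atpF	13757	C92	P31→H31	C→T	2
rps2	16983	C248	S83→L83	C→T	2
rps2	17097	C134	T45→I45	C→T	2
rpoC2	17886	C3728	S1243→L1243	C→T	2
rpoC2	18765	C2849	S950→F950	C→T	2
rpoC1	24531	C62	S21→L21	C→T	2
psbZ	37856	C50	S17→L17	C→T	2
ndhK	52675	C81	F27→F27	C→T	3
ndhC	52958	C40	L14→L14	C→T	1
atpB	56330	C23	S8→F8	C→T	2
psaI	61448	C80	S27→F27	C→T	2
psbF	66719	C77	S26→F26	C→T	2
psbE	66843	C214	P72→S72	C→T	1
rps18	70747	C221	S74→L74	C→T	2
petB	78764	C611	P204→L204	C→T	2
rpoA	81234	C200	S67→F67	C→T	2
rps8	82841	C182	P61→L61	C→T	2
ndhB	97156	C1481	P494→L494	C→T	2
ndhB	97807	C830	S277→L277	C→T	2
ndhB	98570	C746	S249→F249	C→T	2
ndhB	98579	C737	P246→L246	C→T	2
ndhB	98705	C611	S204→L204	C→T	2
ndhB	98729	C586	H196→Y196	C→T	1
ndhB	98848	C467	P156→L156	C→T	2
ndhB	99167	C149	S50→L50	C→T	2
ndhF	114736	C290	S97→L97	C→T	2
ndhD	118369	C1310	S437→L437	C→T	2
ndhD	118792	C887	P296→L296	C→T	2
ndhD	118801	C878	S293→L293	C→T	2
ndhD	119005	C674	S225→L225	C→T	2
ndhD	119296	C383	S128→L128	C→T	2
ndhA	124204	C341	S114→L114	C→T	2
ndhH	125201	C505	H169→Y169	C→T	1
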