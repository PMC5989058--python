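patient	age	crypts	wpc	ppc
S000	61.13311466139669	76083	28	5
S001	29.03876837232312	7223	0	1
S002	39.41058640118757	7069	2	0
S003	15.77712643035888	29516	2	5
S004	77.38873882462143	19200	14	2
S005	88.32059454732325	77452	32	7
S006	77.29678362957888	7270	3	1
S007	56.733280996945275	17291	4	4
S008	12.309844698142992	12330	1	2
S009	59.32121715193355	25033	8	3
S010	29.485337625958792	13557	1	1
S011	58.1829687659624	10884	4	0
S012	35.030271818294	9446	2	2
S013	62.293747111878744	35385	7	4
S014	16.593412267645995	19259	0	2
S015	36.0374440790052	23625	1	3
S016	34.04489923258312	64105	11	4
S017	53.570203602246636	51209	19	2
S018	40.14532794721979	21374	1	3
S019	17.924301233635006	11201	1	1
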