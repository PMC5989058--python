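patient	age	patch_size
S000	61.13311466139669	1
S000	61.13311466139669	2
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	4
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	4
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	1
S000	61.13311466139669	2
S000	61.13311466139669	1
S000	61.13311466139669	1
S002	39.41058640118757	1
S002	39.41058640118757	1
S003	15.77712643035888	1
S003	15.77712643035888	1
S004	77.38873882462143	3
S004	77.38873882462143	1
S004	77.38873882462143	1
S004	77.38873882462143	1
S004	77.38873882462143	2
S004	77.38873882462143	1
S004	77.38873882462143	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	2
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	2
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	3
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	2
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	1
S005	88.32059454732325	2
S005	88.32059454732325	2
S005	88.32059454732325	1
S005	88.32059454732325	3
S005	88.32059454732325	1
S005	88.32059454732325	2
S005	88.32059454732325	2
S005	88.32059454732325	1
S006	77.29678362957888	1
S006	77.29678362957888	1
S006	77.29678362957888	1
S007	56.733280996945275	1
S007	56.733280996945275	1
S007	56.733280996945275	2
S007	56.733280996945275	1
S007	56.733280996945275	1
S007	56.733280996945275	1
S007	56.733280996945275	1
S007	56.733280996945275	1
S007	56.733280996945275	3
S007	56.733280996945275	1
S007	56.733280996945275	1
S009	59.32121715193355	1
S009	59.32121715193355	1
S009	59.32121715193355	2
S009	59.32121715193355	1
S009	59.32121715193355	2
S009	59.32121715193355	1
S009	59.32121715193355	2
S009	59.32121715193355	1
S009	59.32121715193355	1
S011	58.1829687659624	1
S011	58.1829687659624	1
S011	58.1829687659624	1
S011	58.1829687659624	3
S011	58.1829687659624	2
S011	58.1829687659624	1
S012	35.030271818294	1
S012	35.030271818294	1
S012	35.030271818294	1
S013	62.293747111878744	1
S013	62.293747111878744	1
S013	62.293747111878744	1
S013	62.293747111878744	2
S013	62.293747111878744	2
S013	62.293747111878744	1
S013	62.293747111878744	1
S013	62.293747111878744	1
S013	62.293747111878744	1
S013	62.293747111878744	1
S013	62.293747111878744	2
S013	62.293747111878744	1
S013	62.293747111878744	1
S013	62.293747111878744	1
S014	16.593412267645995	1
S014	16.593412267645995	1
S015	36.0374440790052	1
S015	36.0374440790052	1
S015	36.0374440790052	1
S015	36.0374440790052	2
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S016	34.04489923258312	1
S017	53.570203602246636	1
S017	53.570203602246636	1
S017	53.570203602246636	4
S017	53.570203602246636	2
S017	53.570203602246636	2
S017	53.570203602246636	1
S017	53.570203602246636	1
S017	53.570203602246636	1
S017	53.570203602246636	1
S017	53.570203602246636	1
S017	53.570203602246636	1
S017	53.570203602246636	1
S018	40.14532794721979	1
S018	40.14532794721979	3
S018	40.14532794721979	1
S018	40.14532794721979	1
S018	40.14532794721979	1
S018	40.14532794721979	2
S018	40.14532794721979	1
S018	40.14532794721979	1
S019	17.924301233635006	1
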