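patient	block	ta_clones	goblet_cells
T0	B0	2	1073908
T0	B1	2	841406
T0	B2	7	1875480
T1	B0	6	1480245
T1	B1	6	1273878
T1	B2	10	2150003
T2	B0	4	1599982
T2	B1	6	1456215
T2	B2	4	1584403
T3	B0	2	856520
T3	B1	6	1317603
T3	B2	0	1208986
T4	B0	2	1222957
T4	B1	10	1500067
T4	B2	7	1920772
T5	B0	4	1527202
T5	B1	5	2550579
T5	B2	8	2829187
T6	B0	6	1245257
T6	B1	11	2330660
T6	B2	10	1350697
T7	B0	6	1306207
T7	B1	8	1412512
T7	B2	15	1722585
T8	B0	16	1670367
T8	B1	15	2363362
T8	B2	8	1197230
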