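patient_id	cohort	mean_fev1	fev1_sd	exacerbations
201	paediatric	84.4	2.7	3
203	paediatric	100.2	10.7	1
212	paediatric	83.9	6.3	4
213	paediatric	82.3	15.7	3
216	paediatric	117.8	5.2	1
217	paediatric	100.4	2.7	0
218	paediatric	89.6	6.6	2
219	paediatric	98.7	1.4	0
223	paediatric	110.0	1.7	0
228	paediatric	99.8	6.2	0
233	paediatric	71.2	9.9	1
240	paediatric	60.6	6.3	1
242	paediatric	74.7	8.6	2
245	paediatric	92.0	14.2	3
246	paediatric	91.0	9.1	2
101	adult	64.2	2.1	7
103	adult	79.7	7.9	1
104	adult	77.9	7.5	2
106	adult	57.2	8.0	8
108	adult	60.7	1.5	2
110	adult	120.1	2.7	1
112	adult	93.2	4.5	1
113	adult	58.1	1.4	3
114	adult	87.1	1.9	0
116	adult	99.6	2.1	0
118	adult	73.8	4.2	3
119	adult	47.9	2.9	3
120	adult	78.6	3.3	0
121	adult	92.9	3.7	1
140	adult	47.3	6.9	6
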