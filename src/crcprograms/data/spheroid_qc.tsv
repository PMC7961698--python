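patient	mean_reads_per_cell	cells_after_qc	mean_genes_per_cell	lgr5_score
P1	348016	325	3535	12.85
P2	261595	309	4072	0.23
P3	460471	551	4537	6.43
P4	1061813	263	4186	87.72
P5	334099	502	3943	4.61
P6	1276856	141	5116	0.03
P7	359362	434	4335	10.18
P8	190170	197	4174	3.38
P9	527407	464	4354	0.00
P10	391680	736	3418	3.35
P11	505439	308	4036	1.43
P12	454258	433	3977	0.00
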