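sample	mean_reads_per_cell	cells_after_qc	epithelial_cells	mean_genes_per_cell
O1	120218	5550		5542
O2	169086	3003		5425
O3	73415	8785		4176
X1	238836	1475		1841
X2	237891	1070		4598
T1	1333884	362	136	3646
T2	847472	538	77	4090
T3	623942	724	40	2474
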