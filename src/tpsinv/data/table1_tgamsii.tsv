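# Terpene synthase gene inventory of the T. gamsii T6085 genome (16 genes),
# mapped onto the default functional taxonomy. ``override`` may force
# include/exclude in expression-candidate selection (empty = rule decides).
# Columns: jgi_id  name  group_id  subtype  override
Trigam1|5596	TC4	had_bifunctional
Trigam1|4742	TRI5	tri5
Trigam1|162	TS5	pentalenene
Trigam1|9843	TS7	tri5_unchar1
Trigam1|1824	TS4	tri5_unchar2
Trigam1|4947	TS3	tsc_unchar3
Trigam1|5367	TS1	tsc_unchar4
Trigam1|340	TS6	squalene_synthase
Trigam1|3208	TC3	protein_prenylation	GGTase1
Trigam1|5139	TC5	protein_prenylation	GGTase2
Trigam1|3927	TC1	protein_prenylation	FTase
Trigam1|4065	TS8	polyprenyl_superfamily	GGPP_synthase
Trigam1|2917	TS10	polyprenyl_superfamily	FPP_synthase
Trigam1|9898	TS9	polyprenyl_superfamily	indole_diTS
Trigam1|8345	TC2	oxidosqualene_cyclase
Trigam1|6072	TS11	sqs_psy_unchar5
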