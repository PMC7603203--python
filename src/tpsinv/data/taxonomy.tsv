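# Default 15-leaf functional taxonomy of the Trichoderma terpene synthase family.
# Columns (tab-separated):
#   id  display_name  required_domains  required_motifs  forbidden_domains  needs_tm  precedence
# required_domains: |-separated requirements; a comma inside one requirement is an
# any-of set. UNCHAR1..UNCHAR5, INDOLE_DITS and CHIMERIC_LIKE are placeholder
# cluster accessions standing in for phylogenetic-cluster evidence on
# uncharacterized groups and subtypes (no public database signature exists).
had_bifunctional	HAD-like bifunctional TS	PF13419|PTHR43611:SF3|IPR008930	DDxxE,DxDTT		0	1
tri5	trichodiene synthase	PF06330|PIRSF001388	tri5_aspartate,tri5_triad		0	2
longiborneol	longiborneol synthase	PF06330	DDHFD_family		0	3
tri5_unchar1	uncharacterized group 1	PF06330|UNCHAR1			0	4
tri5_unchar2	uncharacterized group 2	PF06330|UNCHAR2			0	5
presilphiperfolanol	presilphiperfolan-8b-ol synthase	PF03936	DDxxD		0	6
pentalenene	pentalenene synthase	PF03936	NSD,DTE		0	7
tsc_unchar3	uncharacterized group 3	PF03936|UNCHAR3			0	8
tsc_unchar4	uncharacterized group 4	PF03936|UNCHAR4			0	9
squalene_synthase	squalene synthase	PF00494|PTHR11626:SF2|PS01044			1	10
protein_prenylation	protein prenylation enzymes	PTHR11774:SF4,PTHR11774:SF11,PTHR11774:SF6			0	11
oxidosqualene_cyclase	oxidosqualene cyclase	PF13249|PF13243|PTHR11764|PS01074	DCTAE_family,QW		0	12
sqs_psy_unchar5	uncharacterized group 5	PF00494|PTHR21181:SF13			0	13
class2_diterpene	Class II diterpene synthase (CPS/KS-like)	PTHR31739:SF4|PIRSF026498	DxDD		0	14
polyprenyl_superfamily	polyprenyl synthase superfamily	PF00348	DDxxD		0	15
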