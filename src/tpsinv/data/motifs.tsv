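# Bundled motif set: name, grammar, fold_class (tab-separated).
# Aspartate-rich metal-binding motifs and accessory structural motifs of
# fungal terpene cyclases and prenyl transferases.
class1_generic	D[DE]xx[DE]	class_I
DDxxD	DDxxD	class_I
DDxxE	DDxxE	class_I
DxDD	DxDD	class_II
DxDTT	DxDTT	class_II
tri5_aspartate	DDS[RI]E	class_I
tri5_triad	NDLFSFYKE	accessory
DDHFD_family	[DN][DE]HFD	class_I
DCTAE_family	DC[TI][AS]E	class_II
QW	QW	accessory
NSD	NSD	accessory
DTE	DTE	accessory
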