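# rxn_id	subsystem	lb	ub	equation
EX_GA3P	uptake	0	10	 -> 1 ga3p_c
EX_PYR	uptake	0	10	 -> 1 pyr_c
DXS	terpenoid backbone	0	10	1 ga3p_c + 1 pyr_c -> 1 dxp_c
GGPP_SYN	terpenoid backbone	1	1	1 dxp_c -> 1 ggpp_c
PSY	carotenoid biosynthesis	0	10	1 ggpp_c -> 1 phytoene_c
FUCO_SYN	carotenoid biosynthesis	0	10	1 phytoene_c -> 1 fuco_c
EX_FUCO	carotenoid biosynthesis	0	10	1 fuco_c -> 
GGR	porphyrin and chlorophyll metabolism	0	10	1 ggpp_c -> 1 phytylpp_c
CHLIDE_SYN	porphyrin and chlorophyll metabolism	0	10	1 ga3p_c -> 1 chlide_c
CHLG	porphyrin and chlorophyll metabolism	0	10	1 phytylpp_c + 1 chlide_c -> 1 chla_c
EX_CHLA	porphyrin and chlorophyll metabolism	0	10	1 chla_c -> 
PDH	lipid metabolism	0	10	1 pyr_c -> 1 accoa_c
FAS	lipid metabolism	0	10	1 accoa_c -> 1 fa_c
EX_FA	lipid metabolism	0	10	1 fa_c -> 
DISC_IN	disconnected control	0	5	 -> 1 orphan_c
DISC_OUT	disconnected control	0	5	1 orphan_c -> 
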