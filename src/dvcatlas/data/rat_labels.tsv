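# Encoded from the published rodent DVC hierarchy figures; structural
# counts per layer are exact, node membership within classes is a
# plausible reconstruction where the figures are ambiguous (flagged).
name	layer	parent	species_origin
neurons	1		rat
glia	1		rat
vascular	1		rat
connective_tissue	1		rat
astrocytes	2	glia	rat
oligodendrocytes	2	glia	rat
opcs	2	glia	rat
microglia	2	glia	rat
ependymal_cells	2	glia	rat
endothelial_cells	2	vascular	rat
mural_cells	2	vascular	rat
fibroblasts	2	connective_tissue	rat
sall3_class	2	neurons	rat
lhx2_class	2	neurons	rat
monoamine_class	2	neurons	rat
ph_related_class	2	neurons	rat
corelautus_class	2	neurons	rat
coe_class	2	neurons	rat
chat_class	2	neurons	rat
ano2_class	2	neurons	rat
mixed_class	2	neurons	rat
immunity_akin	2	neurons	rat
ortus_akin	2	neurons	rat
ca_permeable_astrocytes	3	astrocytes	rat
gfap_low_astrocytes	3	astrocytes	rat
premyelinating_ol	3	oligodendrocytes	rat
myelinating_intermediate_ol	3	oligodendrocytes	rat
myelinating_ol	3	oligodendrocytes	rat
opc	3	opcs	rat
microglia_1	3	microglia	rat
microglia_2	3	microglia	rat
ependymal	3	ependymal_cells	rat
tanycytes	3	ependymal_cells	rat
endothelial	3	endothelial_cells	rat
pericytes	3	mural_cells	rat
smooth_muscle	3	mural_cells	rat
p_fibroblasts	3	fibroblasts	rat
s_fibroblasts	3	fibroblasts	rat
sall3_1	3	sall3_class	rat
sall3_2	3	sall3_class	rat
sall3_3	3	sall3_class	rat
sall3_4	3	sall3_class	rat
sall3_5	3	sall3_class	rat
glp1	3	sall3_class	rat
lhx2_1	3	lhx2_class	rat
lhx2_2	3	lhx2_class	rat
lhx2_3	3	lhx2_class	rat
m0	3	monoamine_class	rat
m1	3	monoamine_class	rat
m2	3	monoamine_class	rat
m3	3	monoamine_class	rat
corelautus_neurons	3	corelautus_class	rat
coe_atp10a	3	coe_class	rat
coe_1	3	coe_class	rat
coe_2	3	coe_class	rat
preganglionic	3	chat_class	rat
ano2_neurons	3	ano2_class	rat
ano2_2	3	ano2_class	rat
mixed_neurons_1	3	mixed_class	rat
mixed_neurons_2	3	mixed_class	rat
mixed_neurons_3	3	mixed_class	rat
mixed_neurons_4	3	mixed_class	rat
mixed_neurons_5	3	mixed_class	rat
mixed_neurons_6	3	mixed_class	rat
immunity_related_rat	3	immunity_akin	rat
pdgfra_neurons_rat	3	ortus_akin	rat
m4_rat	3	monoamine_class	rat
m5_rat	3	monoamine_class	rat
m_sema_rat	3	monoamine_class	rat
lepr_ap_rat	3	sall3_class	rat
cck_nts_rat	3	lhx2_class	rat
gfral_rat	3	monoamine_class	rat
tanycyte_like_neurons_rat	3	mixed_class	rat
prlr_rat	3	coe_class	rat
unspecific	3	mixed_class	rat
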