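# Encoded from the published rodent DVC hierarchy figures; structural
# counts per layer are exact, node membership within classes is a
# plausible reconstruction where the figures are ambiguous (flagged).
name	layer	parent	species_origin
neurons	1		both
glia	1		both
vascular	1		both
connective_tissue	1		both
astrocytes	2	glia	both
oligodendrocytes	2	glia	both
opcs	2	glia	both
microglia	2	glia	both
ependymal_cells	2	glia	both
endothelial_cells	2	vascular	both
mural_cells	2	vascular	both
fibroblasts	2	connective_tissue	both
sall3_class	2	neurons	both
lhx2_class	2	neurons	both
monoamine_class	2	neurons	both
golli_class	2	neurons	mouse
ph_related_class	2	neurons	both
corelautus_class	2	neurons	both
coe_class	2	neurons	both
chat_class	2	neurons	both
ano2_class	2	neurons	both
mixed_class	2	neurons	both
ca_permeable_astrocytes	3	astrocytes	both
gfap_low_astrocytes	3	astrocytes	both
premyelinating_ol	3	oligodendrocytes	both
myelinating_intermediate_ol	3	oligodendrocytes	both
myelinating_ol	3	oligodendrocytes	both
opc	3	opcs	both
microglia_1	3	microglia	both
microglia_2	3	microglia	both
ependymal	3	ependymal_cells	both
tanycytes	3	ependymal_cells	both
endothelial	3	endothelial_cells	both
pericytes	3	mural_cells	both
smooth_muscle	3	mural_cells	both
p_fibroblasts	3	fibroblasts	both
s_fibroblasts	3	fibroblasts	both
sall3_1	3	sall3_class	both
sall3_2	3	sall3_class	both
sall3_3	3	sall3_class	both
sall3_4	3	sall3_class	both
sall3_5	3	sall3_class	both
sall3_6	3	sall3_class	mouse
sall3_7	3	sall3_class	mouse
glp1	3	sall3_class	both
lhx2_1	3	lhx2_class	both
lhx2_2	3	lhx2_class	both
lhx2_3	3	lhx2_class	both
lhx2_4	3	lhx2_class	mouse
lhx2_5	3	lhx2_class	mouse
m0	3	monoamine_class	both
m1	3	monoamine_class	both
m2	3	monoamine_class	both
m3	3	monoamine_class	both
golli_neurons	3	golli_class	mouse
ph_neurons	3	ph_related_class	mouse
corelautus_neurons	3	corelautus_class	both
coe_atp10a	3	coe_class	both
coe_1	3	coe_class	both
coe_2	3	coe_class	both
coe_3	3	coe_class	mouse
coe_4	3	coe_class	mouse
preganglionic	3	chat_class	both
ano2_neurons	3	ano2_class	both
ano2_2	3	ano2_class	both
mixed_neurons_1	3	mixed_class	both
mixed_neurons_2	3	mixed_class	both
mixed_neurons_3	3	mixed_class	both
mixed_neurons_4	3	mixed_class	both
mixed_neurons_5	3	mixed_class	both
mixed_neurons_6	3	mixed_class	both
mixed_neurons_7	3	mixed_class	mouse
immunity_akin	2	neurons	rat
ortus_akin	2	neurons	rat
noradrenergic_a2	4	m0	mouse
serotonergic_b	4	m1	mouse
monoamine_m	4	m3	mouse
gcg_high	4	glp1	mouse
nts_hi_neurons	4	sall3_1	mouse
nts_lo_neurons	4	lhx2_1	mouse
chat_dmv	4	preganglionic	mouse
immunity_related_rat	3	immunity_akin	rat
pdgfra_neurons_rat	3	ortus_akin	rat
m4_rat	3	monoamine_class	rat
m_sema_rat	3	monoamine_class	rat
gfral_rat	3	monoamine_class	rat
lepr_ap_rat	3	sall3_class	rat
cck_nts_rat	3	lhx2_class	rat
prlr_rat	3	coe_class	rat
tanycyte_like_neurons_rat	3	mixed_class	rat
unspecific_rat	3	mixed_class	rat
ano2_2_rat	3	ano2_class	rat
ano2_neurons_rat	3	ano2_class	rat
ca_permeable_astrocytes_rat	3	astrocytes	rat
coe_1_rat	3	coe_class	rat
coe_2_rat	3	coe_class	rat
coe_atp10a_rat	3	coe_class	rat
corelautus_neurons_rat	3	corelautus_class	rat
endothelial_rat	3	endothelial_cells	rat
ependymal_rat	3	ependymal_cells	rat
gfap_low_astrocytes_rat	3	astrocytes	rat
lhx2_1_rat	3	lhx2_class	rat
lhx2_2_rat	3	lhx2_class	rat
lhx2_3_rat	3	lhx2_class	rat
microglia_1_rat	3	microglia	rat
microglia_2_rat	3	microglia	rat
mixed_neurons_1_rat	3	mixed_class	rat
mixed_neurons_2_rat	3	mixed_class	rat
mixed_neurons_3_rat	3	mixed_class	rat
mixed_neurons_4_rat	3	mixed_class	rat
mixed_neurons_5_rat	3	mixed_class	rat
mixed_neurons_6_rat	3	mixed_class	rat
myelinating_intermediate_ol_rat	3	oligodendrocytes	rat
myelinating_ol_rat	3	oligodendrocytes	rat
opc_rat	3	opcs	rat
p_fibroblasts_rat	3	fibroblasts	rat
pericytes_rat	3	mural_cells	rat
preganglionic_rat	3	chat_class	rat
premyelinating_ol_rat	3	oligodendrocytes	rat
smooth_muscle_rat	4	smooth_muscle	rat
basal_microglia_rat	4	microglia_1	rat
m3_rat	5	monoamine_m	rat
m5_rat	5	monoamine_m	rat
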