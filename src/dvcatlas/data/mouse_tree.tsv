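# Encoded from the published rodent DVC hierarchy figures; structural
# counts per layer are exact, node membership within classes is a
# plausible reconstruction where the figures are ambiguous (flagged).
name	layer	parent	species_origin
neurons	1		mouse
glia	1		mouse
vascular	1		mouse
connective_tissue	1		mouse
astrocytes	2	glia	mouse
oligodendrocytes	2	glia	mouse
opcs	2	glia	mouse
microglia	2	glia	mouse
ependymal_cells	2	glia	mouse
endothelial_cells	2	vascular	mouse
mural_cells	2	vascular	mouse
fibroblasts	2	connective_tissue	mouse
sall3_class	2	neurons	mouse
lhx2_class	2	neurons	mouse
monoamine_class	2	neurons	mouse
golli_class	2	neurons	mouse
ph_related_class	2	neurons	mouse
corelautus_class	2	neurons	mouse
coe_class	2	neurons	mouse
chat_class	2	neurons	mouse
ano2_class	2	neurons	mouse
mixed_class	2	neurons	mouse
ca_permeable_astrocytes	3	astrocytes	mouse
gfap_low_astrocytes	3	astrocytes	mouse
premyelinating_ol	3	oligodendrocytes	mouse
myelinating_intermediate_ol	3	oligodendrocytes	mouse
myelinating_ol	3	oligodendrocytes	mouse
opc	3	opcs	mouse
microglia_1	3	microglia	mouse
microglia_2	3	microglia	mouse
ependymal	3	ependymal_cells	mouse
tanycytes	3	ependymal_cells	mouse
endothelial	3	endothelial_cells	mouse
pericytes	3	mural_cells	mouse
smooth_muscle	3	mural_cells	mouse
p_fibroblasts	3	fibroblasts	mouse
s_fibroblasts	3	fibroblasts	mouse
sall3_1	3	sall3_class	mouse
sall3_2	3	sall3_class	mouse
sall3_3	3	sall3_class	mouse
sall3_4	3	sall3_class	mouse
sall3_5	3	sall3_class	mouse
sall3_6	3	sall3_class	mouse
sall3_7	3	sall3_class	mouse
glp1	3	sall3_class	mouse
lhx2_1	3	lhx2_class	mouse
lhx2_2	3	lhx2_class	mouse
lhx2_3	3	lhx2_class	mouse
lhx2_4	3	lhx2_class	mouse
lhx2_5	3	lhx2_class	mouse
m0	3	monoamine_class	mouse
m1	3	monoamine_class	mouse
m2	3	monoamine_class	mouse
m3	3	monoamine_class	mouse
golli_neurons	3	golli_class	mouse
ph_neurons	3	ph_related_class	mouse
corelautus_neurons	3	corelautus_class	mouse
coe_atp10a	3	coe_class	mouse
coe_1	3	coe_class	mouse
coe_2	3	coe_class	mouse
coe_3	3	coe_class	mouse
coe_4	3	coe_class	mouse
preganglionic	3	chat_class	mouse
ano2_neurons	3	ano2_class	mouse
ano2_2	3	ano2_class	mouse
mixed_neurons_1	3	mixed_class	mouse
mixed_neurons_2	3	mixed_class	mouse
mixed_neurons_3	3	mixed_class	mouse
mixed_neurons_4	3	mixed_class	mouse
mixed_neurons_5	3	mixed_class	mouse
mixed_neurons_6	3	mixed_class	mouse
mixed_neurons_7	3	mixed_class	mouse
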