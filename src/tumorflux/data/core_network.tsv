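# Reduced central-carbon network, calibrated against the phenotype flux table.
# Effective lumped stoichiometry; fluxes in mmol/g-DW-hr, biomass flux in 1/hr.
# Compartment suffixes: _e extracellular, _c cytosol, _m mitochondrion.
#
# Calibrated coefficients (see docs/methods.md):
#   glycolysis net: hexose -> 2 pyruvate + 2 ATP + 2 NADH
#   oxidation yields: 2.3 ATP per cytosolic NADH, 6.7 ATP per mitochondrial
#   pyruvate (effective aerobic yield 20 ATP per glucose)
#   biomass template (per g-DW): 2.07224 hexose + 6.72 akg + 6.10587 NADH
#   + 102.73973 ATP
#   glutaminolysis: gln -> akg + 3 NADH; akg oxidation 2.9826 O2 -> 6.6324 ATP
#
# biomass_fractions	amino_acids=0.78	nucleotides=0.06	lipids=0.16
# maintenance_rate	5.0
id	name	equation	lb	ub	kind
EX_glc	glucose exchange	glc_e <=>	-inf	inf	exchange
EX_o2	oxygen exchange	o2_e <=>	-inf	inf	exchange
EX_lac	lactate exchange	lac_e <=>	0	inf	exchange
EX_gln	glutamine exchange	gln_e <=>	0	inf	exchange
GLCt	glucose transport	glc_e --> hex_c	0	inf	transport
O2t	oxygen transport	o2_e --> o2_c	0	inf	transport
LACt	lactate transport	lac_c <=> lac_e	-inf	inf	transport
GLNt	glutamine transport	gln_e --> gln_c	0	inf	transport
GLYCu	upper glycolysis	hex_c + 2 atp_c --> 2 g3p_c	0	inf	internal
GLYCl	lower glycolysis	g3p_c --> pyr_c + 2 atp_c + nadh_c	0	inf	internal
LDH	lactate dehydrogenase	pyr_c + nadh_c <=> lac_c	-inf	inf	internal
PYRtm	pyruvate mitochondrial import	pyr_c --> pyr_m	0	inf	transport
PYRox	pyruvate oxidation (PDH + TCA + OXPHOS)	pyr_m + 2.5 o2_c --> 6.7 atp_c	0	inf	internal
NADHox	cytosolic NADH oxidation (shuttle + OXPHOS)	nadh_c + 0.5 o2_c --> 2.3 atp_c	0	inf	internal
ANAPm	anaplerosis (pyruvate carboxylation)	pyr_m --> akg_m	0	inf	internal
GLS	glutaminolysis	gln_c --> akg_m + 3 nadh_c	0	inf	internal
AKGox	alpha-ketoglutarate oxidation	akg_m + 2.9826 o2_c --> 6.6324 atp_c	0	inf	internal
BIOMASS	biomass template	2.07224 hex_c + 6.72 akg_m + 6.10587 nadh_c + 102.73973 atp_c -->	0	inf	biomass
MAINT	maintenance ATP hydrolysis	atp_c -->	0	inf	maintenance
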