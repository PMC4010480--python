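gene_symbol	location	pcsr	expression_class	Breast_M	Breast_D	Endometrial_M	Endometrial_D	Ovarian_M	Ovarian_D	Prostate_M	Prostate_D	Testicular_M	Testicular_D	Colorectal_M	Colorectal_D	Liver_M	Liver_D	Gastric_M	Gastric_D	Pancreatic_M	Pancreatic_D	Glioblastoma_M	Glioblastoma_D	Lung_M	Lung_D
GAPDH	chr12p13.31	1	I	up		up		up	up		up	up		up	up	up	up	up	up		up			up	up
CKS2	chr9q22.2	1	I	up		up		up				up		up		up		up		up				up	
CEP55	chr10q23.33	1	I			up		up				up		up		up		up		up				up	
UHRF1	chr19p13.3	1	I	up		up		up				up		up		up		up		up		up		up	
RRM2	chr2p25.1	1	I	up		up		up				up		up		up		up				up	up	up	
TUBA1B	chr12q13.12	0	I	up		up	up	up	up		up		up	up		up	up	up	up		up		up	up	up
THY1	chr11q23.3	0	I	up		up		up		up		up		up		up		up						up	
AURKA	chr20q13.2	1	I			up		up				up		up		up		up		up				up	
FLJ39632	chr14q11.2	1	I			up		up		up		up		up		up		up				up		up	
FAM83D	chr20q11.23	1	I	up		up		up				up		up		up		up		up				up	
MAD2L1	chr4q27	1	I	up		up		up				up		up		up		up				up		up	
NEK2	chr1q32.3	1	I			up		up				up		up		up		up				up		up	
ASPA	chr17p13.32	0	II	down		down		down		down				down		down		down						down	
CXCL12	chr10q11.21	0	II	down		down		down				down		down		down		down				down		down	
PTGDS	chr9q34.3	0	II	down				down				down		down		down								down	
MALAT1	chr11q13.1	0	II	down	down	down		down		down		down	down	down		down	down	down		down	down	down		down	down
ZEB2	chr2q22.3	1	III	down		down		down		down		down		down				up				down		down	
ZEB1	chr10p11.22	0	III			down		down		up		down		down		up		up				up		down	
KRT8	chr12q13.13	0	III	up		up	up			up	up	up		down	up	down	up		up		up		up	up	up
ANXA2	chr15q22.2	1	III			up	up	down			up	down				up	up	up		up	up		up		
IGF2BP3	chr7p11	1	III			up		up		up		up		up		up		up		up		down		up	
DDX5	chr17q23.3	0	III			down	down	down			down	up	down	down									down	down	down
CD24	chryq11.22	1	III	up		up	up	up		up	down	up	up		down	up		down					up	up	
TOP2A	chr17q21.2	1	III	down		up		up				up		up		up		up		up		up		up	
DCN	chr12q21.33	1	III			down		down		down		down		down		down			down	up			down	down	down
CENPF	chr1q41	0	III	up		up		up				up		up		up		up				up		up	
LIFR	chr5p13.1	1	III	down		down		down				up		down		down		down						down	
ABCA8	chr17q24.2	1	III	down		down		down		up		down		down		down		down						down	
COL11A1	chr1p21.1	1	III	up		up		down				up		up		up		up		up				up	
RSAD2	chr2p25.2	1	III	up		up		up				up		down				down		up		up			
Cd36	chr7q21.11	1	III	down		down		down		up				down				down				up			
PCDH7	chr4p15.1	1	III	up		down		up		up		up		down						up				up	
PKIB	chr6q22.31	1	III	up		down				down		up		down		up		down		down		down		up	
EDNRB	chr13q22.3	1	III	up		up		up		up		up		up		up						down		up	
SULF1	chr8q13.1	1	III	up		up		down				down		up		up		up		up		up		up	
DIO2	chr14q31.1	1	III	up				up		up		down		up				up		up				up	
TMC5	chr16p12.3	1	III	up		up		up		up		down				up				up				down	
HS6ST2	chrXq26.2	1	III			down		down		down		up		up		up		up		down				up	
PTGS2	chr1q31.1	1	III	down				down				down				down				up				down	
GPM6A	chr4q34.2	1	III	down		down		down		down		up		down		down						up		down	
C7	chr5p13.1	1	III	down		down	down	down		down			down	down		down						up		down	
MT1M	chr16q12.2	1	III	down						down		up		down		down		down				up		down	
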