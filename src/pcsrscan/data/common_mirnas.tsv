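mirna	location	pcsr	Breast	Cervical	Endometrial	Ovarian	Prostate	Testicular	Renal	Colorectal	Gastric	Liver	Pancreatic	Glioblastoma	Lung	IntestinalNeuroendocrine	Bladder
hsa-mir-200c	12p13.31	1		up		up	up		down								up
hsa-mir-141	12p13.31	1				up	up		down								up
hsa-mir-106a	Xq26.2	1				up	up		down								up
hsa-mir-20b	Xq26.2	1				up	up		down								up
hsa-mir-30c-2	6q13	1	down	down	down	down		down	down	down					down		
hsa-mir-30a	6q13	1		down					down								down
hsa-mir-500	Xp11.23	0		down					down							up	up
hsa-mir-532	Xp11.23	0		down					down							up	
hsa-mir-501	Xp11.23	0		down					down								up
hsa-mir-502	Xp11.23	0		down					down							up	
hsa-mir-362	Xp11.23	0		down					down								up
hsa-mir-432	14q32.2	1		down					down								
hsa-mir-770	14q32.2	1						down		down		down					
hsa-mir-127	14q32.2	1		down					down								down
hsa-mir-379	14q32.31	0		down					down								
hsa-mir-382	14q32.31	0		down					down								down
hsa-mir-134	14q32.31	0		down					down								down
hsa-mir-27b	9q22.32	0		down					down							up	
hsa-let-7d	9q22.32	0			down	down		up	down						down		up
hsa-mir-23b	9q22.32	0		down					down								
hsa-mir-99b	19q13.41	1		down			down		down								up
hsa-mir-125a	19q13.41	1		down			down		down								up
hsa-mir-424	Xq26.3	0		down					down								
hsa-mir-106b	7q22.1	0				up	up		up							up	up
hsa-mir-93	7q22.1	0				up	up		up								up
hsa-mir-149	2q37.3	0		down					down								down/up
hsa-mir-200b	1p36.33	0				up	up		down								up
hsa-mir-21	17q23.1	1	up			up	up	down	up		down						up
hsa-mir-126	9q34.3	0		up		up											
hsa-mir-214	1q24.3	1	up	up	down			down	down			down		down			down
hsa-mir-101-1	1p31.3	1			down	down		up					up	up	down	up	
hsa-miR-182	7q32.2	0				up	up									up	up
mir155HG	21q21.3	1	up		down	up		down			down	up		down	down		
hsa-mir-30e	1p34.2	0		down					down							up	up
hsa-mir-422a	15q22.31	0		down					down							down	up
hsa-mir-132	17p13.3	0				down			down								down
hsa-mir-205	1q32.2	0		down		down/up	down										down/up
hsa-mir-375	2q35	0		up			up										
hsa-mir-1274b	19q13.43	0		up			up										up
hsa-mir-361	Xq21.2	0		down					down							up	down/up
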