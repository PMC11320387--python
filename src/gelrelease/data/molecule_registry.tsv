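symbol	name	shape_class	kappa	beta_dG	Dstar_over_Dw_e4
NP	Nitrophenol	linear	0.365102	-7.90	1.5
Pe	Pentane	linear	0.481603	-6.22	4
PeOH	Pentanol	linear	0.424164	-4.44	3.2
NB	Nitrobenzene	planar	0.294118	-7.54	3.6
Ph	Phenol	planar	0.263224	-6.19	2.4
B	Benzene	planar	0.247294	-4.88	3.7
PrOH	Propanol	planar	0.261749	-2.07	6.3
MeOH	Methanol	planar	0.184735	-0.36	27
CCl4	Tetrachloromethane	spherical	0.046486	-8.75	1.12
NPe	Neopentane	spherical	0.000002	-8.43	0.77
Et	Ethane	spherical	0.142804	-3.44	17
Me	Methane	spherical	0.002383	-1.88	71
Ar	Argon	spherical	0.000000	-1.51	135
Ne	Neon	spherical	0.000000	-0.20	810
He	Helium	spherical	0.000000	0.19	1970
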