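code	count	description
J	164	Translation
A	1	RNA processing and modification
K	230	Transcription
L	188	Replication, recombination and repair
B	4	Chromatin structure and dynamics
D	32	Cell cycle control, mitosis and meiosis
Y	0	Nuclear structure
V	33	Defense mechanisms
T	127	Signal transduction mechanisms
M	182	Cell wall/membrane biogenesis
N	64	Cell motility
Z	0	Cytoskeleton
W	0	Extracellular structures
U	62	Intracellular trafficking and secretion
O	109	Posttranslational modification, protein turnover, chaperones
C	215	Energy production and conversion
G	216	Carbohydrate transport and metabolism
E	325	Amino acid transport and metabolism
F	76	Nucleotide transport and metabolism
H	145	Coenzyme transport and metabolism
I	118	Lipid transport and metabolism
P	171	Inorganic ion transport and metabolism
Q	108	Secondary metabolites biosynthesis, transport and catabolism
R	391	General function prediction only
S	229	Function unknown
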