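anticodon	aa	gene_count
AGC	A	25
CGC	A	5
TGC	A	9
ACG	R	7
CCG	R	4
TCG	R	6
CCT	R	5
TCT	R	6
GTT	N	27
ATT	N	2
GTC	D	13
GCA	C	30
CTG	Q	20
TTG	Q	11
CTC	E	8
TTC	E	13
GCC	G	15
CCC	G	7
TCC	G	9
GTG	H	11
AAT	I	14
GAT	I	3
TAT	I	5
AAG	L	12
CAG	L	10
TAG	L	3
CAA	L	7
TAA	L	4
CTT	K	15
TTT	K	17
CAT	M	20
GAA	F	12
AGG	P	10
CGG	P	4
TGG	P	7
AGA	S	11
CGA	S	4
TGA	S	5
GCT	S	8
AGT	T	10
CGT	T	6
TGT	T	6
CCA	W	9
GTA	Y	13
ATA	Y	1
AAC	V	11
CAC	V	16
TAC	V	5
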