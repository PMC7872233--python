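gene	protein_change	effect
BRAF	V600E	GOF
BRAF	V600K	GOF
KRAS	G12D	GOF
KRAS	G12V	GOF
KRAS	G12C	GOF
KRAS	G13D	GOF
KRAS	Q61H	GOF
NRAS	Q61K	GOF
NRAS	Q61R	GOF
NRAS	Q61L	GOF
HRAS	Q61L	GOF
HRAS	G12V	GOF
PIK3CA	E545K	GOF
PIK3CA	E542K	GOF
PIK3CA	H1047R	GOF
AKT1	E17K	GOF
TP53	truncating	LOF
TP53	R175H	LOF
TP53	R248W	LOF
TP53	R273H	LOF
PTEN	truncating	LOF
PTEN	R130Q	LOF
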