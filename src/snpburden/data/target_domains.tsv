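# Target InterPro domains for chromium-tolerance candidate screening.
# Curated from experimentally verified bacterial chromate-resistance genes
# (BacMet database families); one row per accession.
# columns: accession	family	description	mechanism
IPR003370	chrA	Chromate ion transporter (CHR) family	Efflux
IPR001763	chrE	Rhodanese family	Enzyme
IPR005025	chrR	NADH_dh2 family	Enzyme
IPR000415	chrR	NADH_dh2 family	Enzyme
IPR011701	mdrL/yfmO	MFS superfamily	Efflux
IPR011545	recG	DEAD/DEAH box helicase domain	Enzyme
IPR001650	recG	Helicase C-terminal domain	Enzyme
IPR004365	recG	OB-fold nucleic acid binding domain	Enzyme
IPR003959	ruvB	RuvB family AAA+ ATPase core	Enzyme
IPR012301	ruvB	RuvB family	Enzyme
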