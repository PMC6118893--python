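# Revised TALE-class clade registry (clades I-XIX plus unclassified sequences).
# origin: N = newly discovered in this analysis; P / M = described by one of
# the two prior classifications. prior: the previous clade assignment, NONE if
# previously unclassified ('TALE-?' = previously known but unplaced).
clade	species	sequence	letter	origin	prior
TALE-I	S.lamarcki	TALE-I A	A	N	NONE
TALE-I	S.lamarcki	TALE-I B	B	N	NONE
TALE-I	S.lamarcki	TALE-I C	C	N	NONE
TALE-I	C.teleta	Ctel 1513294 24 8		P	TALE-I
TALE-I	H.robusta	TALE-I		N	NONE
TALE-I	P.dumerilii	TALE-I		N	NONE
TALE-I	L.anatina	TALE-I		N	NONE
TALE-I	C.gigas	Cgi TALE2		P	TALE-I
TALE-I	P.fucata	Pfuc 24948 1 11659 JP		P	TALE-I
TALE-I	L.gigantea	Lgig 1414665 30 1		P	TALE-I
TALE-I	P.vulgata	TALE-I		N	NONE
TALE-II	C.gigas	Cgi TALE1		P	TALE-II
TALE-II	P.fucata	Pfuc 13151 1 32296 JP		P	TALE-II
TALE-II	P.fucata	Pfuc 13478 1 32332 JP		P	TALE-II
TALE-III	L.anatina	TALE-III		N	NONE
TALE-III	C.gigas	Cgi TALE3		P	TALE-III
TALE-III	P.fucata	Pfuc 98062 1 56909 JP		P	TALE-III
TALE-III	N.fuscoviridis	SPILE-E		M	NONE
TALE-III	P.vulgata	TALE-III		N	NONE
TALE-IV	S.lamarcki	TALE-IV A1	A1	N	NONE
TALE-IV	S.lamarcki	TALE-IV A2	A2	N	NONE
TALE-IV	S.lamarcki	TALE-IV B	B	N	NONE
TALE-IV	S.lamarcki	TALE-IV AX	AX	N	NONE
TALE-IV	S.lamarcki	TALE-IV AY	AY	N	NONE
TALE-IV	S.kraussi	SPILE-X		M	NONE
TALE-IV	S.kraussi	SPILE-Y		M	NONE
TALE-IV	C.teleta	Ctel 1526117 32 9	A	P	TALE-IV
TALE-IV	C.teleta	Ctel 1505080 24 4	B	P	TALE-IV
TALE-IV	P.dumerilii	TALE-IV B	B	N	NONE
TALE-IV	P.dumerilii	TALE-IV A	A	N	NONE
TALE-IV	C.gigas	Cgi TALE7		P	TALE-IV
TALE-IV	C.gigas	Cgi TALE8		P	TALE-IV
TALE-IV	C.gigas	Cgi TALE14		P	TALE-IV
TALE-IV	P.fucata	Pfuc 1892 1 66137 JP	A	P	TALE-IV
TALE-IV	P.fucata	Pfuc 6497 1 45448 JP	B	P	TALE-VI
TALE-IV	N.fuscoviridis	SPILE-B		M	NONE
TALE-IV	P.vulgata	TALE-IV		N	NONE
TALE-V	C.gigas	Cgi TALE6		P	TALE-V
TALE-V	P.fucata	Pfuc 255 1 07443 JP		P	TALE-V
TALE-VI	C.gigas	Cgi TALE9		P	TALE-VI
TALE-VI	C.gigas	Cgi TALE11		P	TALE-VI
TALE-VI	C.gigas	Cgi TALE12		P	TALE-VI
TALE-VI	C.gigas	Cgi TALE13		P	TALE-VI
TALE-VI	P.fucata	Pfuc 1442 1 22591 JP	A	P	TALE-VI
TALE-VI	P.fucata	Pfuc 22569 1 62158 JP	B	P	TALE-VI
TALE-VI	P.fucata	Pfuc 22555 1 40373 JP	C	P	TALE-VI
TALE-VI	P.fucata	Pfuc 18402 1 40058 JP	D	P	TALE-VI
TALE-VI	P.fucata	Pfuc 10095 1 38990 JP	E	P	TALE-VI
TALE-VI	P.fucata	Pfuc 2547 1 30160 JP	F	P	TALE-VI
TALE-VI	P.fucata	Pfuc 312 1 50785 JP	G	P	TALE-VI
TALE-VII	S.lamarcki	TALE-VII A	A	N	NONE
TALE-VII	S.lamarcki	TALE-VII B	B	N	NONE
TALE-VII	C.gigas	Cgi TALE4		P	TALE-VII
TALE-VII	P.fucata	Pfuc 6013 1 23936 JP		P	TALE-VII
TALE-VIII	S.lamarcki	TALE-VIII A	A	N	NONE
TALE-VIII	S.lamarcki	TALE-VIII B	B	N	NONE
TALE-VIII	S.lamarcki	TALE-VIII C	C	N	NONE
TALE-VIII	S.lamarcki	TALE-VIII D	D	N	NONE
TALE-VIII	S.lamarcki	TALE-VIII E	E	N	NONE
TALE-VIII	S.lamarcki	TALE-VIII F	F	N	NONE
TALE-VIII	S.lamarcki	TALE-VIII G	G	N	NONE
TALE-VIII	S.lamarcki	TALE-VIII H	H	N	NONE
TALE-VIII	S.kraussi	SPILE-Z		M	NONE
TALE-VIII	C.teleta	Ctel 1505086 31 9	B1	P	TALE-VIII
TALE-VIII	C.teleta	Ctel 1505698 31 9	B2	P	TALE-VIII
TALE-VIII	C.teleta	Ctel 1499331 27 4	B3	P	TALE-VIII
TALE-VIII	C.teleta	Ctel 1499505 38 4	A1	P	TALE-IV
TALE-VIII	C.teleta	TALE-VIII A2	A2	M	NONE
TALE-VIII	C.teleta	TALE-VIII C	C	M	NONE
TALE-IX	C.teleta	Ctel 1518266 30 6	A	P	TALE-IX
TALE-IX	C.teleta	Ctel 1518128 28 9	B	P	TALE-IX
TALE-IX	C.teleta	Ctel 1502937 32 5	C	P	TALE-IX
TALE-X	S.lamarcki	TALE-X A	A	N	NONE
TALE-X	S.lamarcki	TALE-X B	B	N	NONE
TALE-XI	S.lamarcki	TALE-XI A	A	N	NONE
TALE-XI	S.lamarcki	TALE-XI B	B	N	NONE
TALE-XI	C.teleta	TALE-XI		N	NONE
TALE-XII	C.teleta	TALE-XII A1	A1	N	NONE
TALE-XII	C.teleta	TALE-XII A2	A2	N	NONE
TALE-XII	C.teleta	TALE-XII A3	A3	N	NONE
TALE-XII	C.teleta	TALE-XII B	B	M	NONE
TALE-XIII	S.lamarcki	TALE-XIII A	A	N	NONE
TALE-XIII	S.lamarcki	TALE-XIII B2	B2	N	NONE
TALE-XIII	C.teleta	TALE-XIII		N	NONE
TALE-XIII	L.anatina	TALE-XIII		N	NONE
TALE-XIII	C.gigas	Cgi TALE5		P	TALE-?
TALE-XIII	P.vulgata	TALE-XIII		N	NONE
TALE-XIV	S.lamarcki	TALE-XIV		N	NONE
TALE-XIV	P.vulgata	TALE-XIV		N	NONE
TALE-XV	L.gigantea	Lgig 1419427 48 9		P	TALE-VI
TALE-XV	N.fuscoviridis	SPILE-C		M	NONE
TALE-XV	P.vulgata	TALE-XV		N	NONE
TALE-XVI	H.robusta	TALE-XVI A	A	N	NONE
TALE-XVI	H.robusta	TALE-XVI B	B	N	NONE
TALE-XVII	L.gigantea	Lgig 1410135 44 3	A	P	TALE-VI
TALE-XVII	L.gigantea	Lgig 1410138 39 8	B	P	TALE-VI
TALE-XVII	N.fuscoviridis	SPILE-A		M	NONE
TALE-XVIII	S.lamarcki	TALE-XVIII		N	Mkx2
TALE-XVIII	C.teleta	TALE-XVIII		M	NONE
TALE-XVIII	L.anatina	TALE-XVIII		N	NONE
TALE-XVIII	N.fuscoviridis	SPILE-D		M	NONE
TALE-XVIII	P.vulgata	TALE-XVIII A	A	N	NONE
TALE-XVIII	P.vulgata	TALE-XVIII B	B	N	NONE
TALE-XIX	H.robusta	TALE-XIX A	A	N	NONE
TALE-XIX	H.robusta	TALE-XIX B	B	N	NONE
TALE-XIX	H.robusta	TALE-XIX C	C	N	NONE
TALE-XIX	H.robusta	TALE-XIX D	D	N	NONE
TALE-XIX	H.robusta	TALE-XIX E	E	N	NONE
TALE-XIX	H.robusta	TALE-XIX F	F	N	NONE
TALE-XIX	H.robusta	TALE-XIX G	G	N	NONE
TALE-XIX	H.robusta	TALE-XIX H	H	N	NONE
TALE-XIX	H.robusta	TALE-XIX I	I	N	NONE
TALE-XIX	H.robusta	TALE-XIX J	J	N	NONE
TALE-XIX	H.robusta	TALE-XIX K	K	N	NONE
TALE-XIX	H.robusta	TALE-XIX L	L	N	NONE
TALE-XIX	H.robusta	TALE-XIX M	M	N	NONE
TALE-XIX	H.robusta	TALE-XIX N	N	N	NONE
TALE-XIX	H.robusta	TALE-XIX O	O	N	NONE
TALE-XIX	H.robusta	TALE-XIX P	P	N	NONE
unclassified	S.lamarcki	TALE-? A	A	N	NONE
unclassified	C.teleta	TALE-? A	A	M	NONE
unclassified	C.teleta	TALE-? C	C	M	NONE
unclassified	C.teleta	TALE-IV-like		M	NONE
unclassified	C.teleta	TALE-IX-like		M	NONE
unclassified	P.dumerilii	TALE-?		N	NONE
unclassified	C.gigas	Cgi TALE10		P	TALE-VI
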