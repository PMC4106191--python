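id	sequence	description
human SP-C	FGIPCCPVHLKRLLIVVVVVVLIVVVIVGALLMGL	Native human SP-C, 35 residues, dipalmitoylated at Cys-5/Cys-6 in vivo
dog SP-C	GIPFCPVHLKRLLIVVVVVVLIVVVIVGALLMGL	Native canine SP-C, 34 residues, one palmitoylcysteine replaced by Phe
pig SP-C	LRIPCCPVNLKRLLVVVVVVVLVVVVIVGALLMGL	Native porcine SP-C, 35 residues
rSP-C	FGIPFFPVHLKRLLIVVVVVVLIVVVIVGALLIGL	Recombinant 35-residue human SP-C variant; Phe for Cys-4/Cys-5 and Ile for Met-32 (alignment numbering)
SP-Css	GIPSSPVHLKRLLIVVVVVVLIVVVIVGALLMGL	34-residue human-sequence mimic; palmitoylcysteines replaced by Ser
SP-Cff	GIPFFPVHLKRLLIVVVVVVLIVVVIVGALLMGL	34-residue human-sequence mimic; palmitoylcysteines replaced by Phe
SP-Css ion-lock 1	GIPSSPVHLKRLLIVVVVVELIVKVIVGALLMGL	SP-Css(E20/K24); Glu(-)-20/Lys(+)-24 salt bridge
SP-Cff ion-lock 1	GIPFFPVHLKRLLIVVVVVELIVKVIVGALLMGL	SP-Cff(E20/K24); Glu(-)-20/Lys(+)-24 salt bridge
SP-C33 UCLA	IPSSPVHLKRLKLLLLLLLLILLLILGALLMGL	33-residue poly-Leu mimic, same sequence as conventional SP-C33
SP-C33 ion-lock 1	IPSSPVHLKRLKLLLLLLLEILLKILGALLMGL	SP-C33(E20/K24); Glu(-)-20/Lys(+)-24 salt bridge
SP-C33 ion-lock 2	IPSSPVHLKRLKLLKLLLEEILLKILGALLMGL	SP-C33(K15/E19; E20/K24); double salt bridge
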