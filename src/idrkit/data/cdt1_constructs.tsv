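name	length	description
WT	297	Wild-type Cdt1 N-terminal IDR (residues 1-297)
PheToLeu	297	All Phe residues of the WT IDR replaced by Leu
PheToAla	297	All Phe residues of the WT IDR replaced by Ala
Uniform	297	Charged residues (K/R/D/E) redistributed uniformly across the IDR
Del1_100	198	WT IDR with residues 1-100 deleted (initiator Met retained)
Del101_200	197	WT IDR with residues 101-200 deleted
Del201_297	200	WT IDR with residues 201-297 deleted
DelCoiledCoil	269	WT IDR with the predicted coiled-coil (residues 196-223) deleted
ScrIDR	297	Random composition-preserving scramble of the WT IDR
IleLeu05	297	Half of all Ile and Leu residues of the WT IDR replaced by Ala
IleLeu10	297	All Ile and Leu residues of the WT IDR replaced by Ala
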