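>WT
MAQPSVAAFFTNRKRAALDDAISIKNRRLVEPAETVSPASAPSQLPAGDQDADLDTLKAA
ATGMRTRSGRTARLIVTAAQESKKKTPAAAKMEPHIKQPKLVQFIKKGTLSPRKQAQSSK
LDEEELQQSSAISEHTPKVNFTITSQQNADNVQRGLRTPTKQILKDASPIKADLRRQLTF
DEVKTKVSRSAKLQELKAVLALKAALEQKRKEQEERNRKLRDAGPSPSKSKMSVQLKEFD
TIELEVLISPLKTFKTPTKIPPPTPDKHELMSPRHTDVSKRLLFSPAKNGSPVKLVE
>PheToLeu
MAQPSVAALLTNRKRAALDDAISIKNRRLVEPAETVSPASAPSQLPAGDQDADLDTLKAA
ATGMRTRSGRTARLIVTAAQESKKKTPAAAKMEPHIKQPKLVQLIKKGTLSPRKQAQSSK
LDEEELQQSSAISEHTPKVNLTITSQQNADNVQRGLRTPTKQILKDASPIKADLRRQLTL
DEVKTKVSRSAKLQELKAVLALKAALEQKRKEQEERNRKLRDAGPSPSKSKMSVQLKELD
TIELEVLISPLKTLKTPTKIPPPTPDKHELMSPRHTDVSKRLLLSPAKNGSPVKLVE
>PheToAla
MAQPSVAAAATNRKRAALDDAISIKNRRLVEPAETVSPASAPSQLPAGDQDADLDTLKAA
ATGMRTRSGRTARLIVTAAQESKKKTPAAAKMEPHIKQPKLVQAIKKGTLSPRKQAQSSK
LDEEELQQSSAISEHTPKVNATITSQQNADNVQRGLRTPTKQILKDASPIKADLRRQLTA
DEVKTKVSRSAKLQELKAVLALKAALEQKRKEQEERNRKLRDAGPSPSKSKMSVQLKEAD
TIELEVLISPLKTAKTPTKIPPPTPDKHELMSPRHTDVSKRLLASPAKNGSPVKLVE
>Uniform
MAQPSVKAAFFTRENKAADLAISKINLREVPAKTVSPDASKAREPSQLPKAGQALTDREK
LAAATGKMTSGRETADKLIVTAAKQSRETPAAKADMPHIQKREPLVQFIKGTLDSPREQK
AQSSLLKQQSREDSAIKSHTPVNKFRETITSDQKQNANVQREKGLTPTQKDILASREPIK
ALQLTFKVTDREVSSAKLQLAVLKREALDAALQKQNLAGREPKSPSSDMSKVQLREFTIK
LVLISPDKLRETFTPTKIPPPTPREDKHLMSPHKTVSLRELFKSDPANGSKPVRELV
>Del1_100
MLVQFIKKGTLSPRKQAQSSKLDEEELQQSSAISEHTPKVNFTITSQQNADNVQRGLRTP
TKQILKDASPIKADLRRQLTFDEVKTKVSRSAKLQELKAVLALKAALEQKRKEQEERNRK
LRDAGPSPSKSKMSVQLKEFDTIELEVLISPLKTFKTPTKIPPPTPDKHELMSPRHTDVS
KRLLFSPAKNGSPVKLVE
>Del101_200
MAQPSVAAFFTNRKRAALDDAISIKNRRLVEPAETVSPASAPSQLPAGDQDADLDTLKAA
ATGMRTRSGRTARLIVTAAQESKKKTPAAAKMEPHIKQPKALKAALEQKRKEQEERNRKL
RDAGPSPSKSKMSVQLKEFDTIELEVLISPLKTFKTPTKIPPPTPDKHELMSPRHTDVSK
RLLFSPAKNGSPVKLVE
>Del201_297
MAQPSVAAFFTNRKRAALDDAISIKNRRLVEPAETVSPASAPSQLPAGDQDADLDTLKAA
ATGMRTRSGRTARLIVTAAQESKKKTPAAAKMEPHIKQPKLVQFIKKGTLSPRKQAQSSK
LDEEELQQSSAISEHTPKVNFTITSQQNADNVQRGLRTPTKQILKDASPIKADLRRQLTF
DEVKTKVSRSAKLQELKAVL
>DelCoiledCoil
MAQPSVAAFFTNRKRAALDDAISIKNRRLVEPAETVSPASAPSQLPAGDQDADLDTLKAA
ATGMRTRSGRTARLIVTAAQESKKKTPAAAKMEPHIKQPKLVQFIKKGTLSPRKQAQSSK
LDEEELQQSSAISEHTPKVNFTITSQQNADNVQRGLRTPTKQILKDASPIKADLRRQLTF
DEVKTKVSRSAKLQEGPSPSKSKMSVQLKEFDTIELEVLISPLKTFKTPTKIPPPTPDKH
ELMSPRHTDVSKRLLFSPAKNGSPVKLVE
>ScrIDR
MLTEDLQKFTPPKRGITTSLEKTSPAASQKPISQLPKDTKKKAPPTEQEAEVKAPGRELE
KDPQLDSIRRLVNAPKVKISQQRRQAVAAGELEAGKEAGLTAVKDKGAEEARRSPKDSLN
FDIRSRSAVASVSKLSPLIDAKLLETLLDTKTARTAPAIKPRMNKQPRDHKTQQTRRQPK
EPAIRTRMKAIQAEAATHSSRKQFTFKGEVELPKSKQKLATANPAQVKTQMLSDLSEPEH
TMLTKNSPARTIQVSQFSRPNFLVDDKFALALSKVKIHLSFDNSLPVVKSSLVLDIA
>IleLeu05
MAQPSVAAFFTNRKRAAADDAASIKNRRLVEPAETVSPASAPSQAPAGDQDADLDTAKAA
ATGMRTRSGRTARLAVTAAQESKKKTPAAAKMEPHIKQPKAVQFAKKGTLSPRKQAQSSK
ADEEELQQSSAISEHTPKVNFTATSQQNADNVQRGARTPTKQALKDASPIKADARRQLTF
DEVKTKVSRSAKAQELKAVAALKAAAEQKRKEQEERNRKLRDAGPSPSKSKMSVQAKEFD
TAELEVAISPLKTFKTPTKAPPPTPDKHEAMSPRHTDVSKRLAFSPAKNGSPVKLVE
>IleLeu10
MAQPSVAAFFTNRKRAAADDAASAKNRRAVEPAETVSPASAPSQAPAGDQDADADTAKAA
ATGMRTRSGRTARAAVTAAQESKKKTPAAAKMEPHAKQPKAVQFAKKGTASPRKQAQSSK
ADEEEAQQSSAASEHTPKVNFTATSQQNADNVQRGARTPTKQAAKDASPAKADARRQATF
DEVKTKVSRSAKAQEAKAVAAAKAAAEQKRKEQEERNRKARDAGPSPSKSKMSVQAKEFD
TAEAEVAASPAKTFKTPTKAPPPTPDKHEAMSPRHTDVSKRAAFSPAKNGSPVKAVE
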