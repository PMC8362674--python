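species,L,T,K,F,R,N
Anagallis minima,7,6,3,7,4,3
Anthoceros punctatus s. l.,7,6,3,7,4,4
Alisma lanceolatum,7,7,4,10,7,6
Alisma plantago-aquatica,7,6,,10,6,7
Agrostis stolonifera,8,5,3,6,6,6
Argentina anserina,7,6,4,6,6,7
Atriplex prostrata,8,6,5,6,7,8
Bidens tripartitus,8,6,4,8,7,8
Bryum ruderale,8,5,4,5,6,5
Carex bohemica,8,6,5,8,5,5
Coleanthus subtilis,8,6,6,9,4,5
Crassula aquatica,8,5,5,9,4,4
Cyperus flavescens,8,7,4,8,6,4
Cyperus fuscus,8,7,4,8,6,5
Cyperus michelianus,8,8,5,8,6,6
Elatine alsinastrum,8,7,5,10,6,5
Elatine hexandra,8,6,2,10,4,4
Elatine hydropiper,8,6,4,10,5,5
Elatine triandra,8,6,5,10,5,5
Eleocharis acicularis,8,5,4,9,5,4
Eleocharis ovata,8,6,5,9,5,5
Equisetum arvense,6,5,,6,5,6
Fossombronia wondraczekii,7,5,3,7,4,4
Gnaphalium uliginosum,7,5,4,7,4,5
Gypsophila muralis,7,6,4,6,4,3
Hypericum humifusum,7,6,2,6,3,3
Illecebrum verticillatum,8,6,2,7,2,2
Isolepis setacea,8,6,2,8,4,3
Juncus bufonius,7,5,3,7,4,4
Juncus capitatus,8,6,2,7,3,2
Juncus ranarius,8,6,5,7,7,5
Juncus tenageia,8,6,3,8,3,3
Laphangium luteoalbum,8,7,3,7,5,4
Limosella aquatica,8,6,4,9,6,6
Lindernia procumbens,8,7,5,9,5,5
Lythrum hyssopifolia,8,7,4,8,7,5
Lythrum portula,7,6,2,8,4,3
Mentha arvensis,7,5,,6,6,6
Mentha pulegium,8,7,4,7,6,6
Montia arvensis,7,5,2,7,4,4
Myosurus minimus,8,6,4,7,5,6
Oxybasis rubra,8,6,4,7,7,8
Persicaria hydropiper,7,6,3,8,5,7
Persicaria lapathifolia s. l.,7,6,,7,6,8
Phaeoceros laevis,7,6,3,7,4,4
Plantago major subsp. intermedia,8,6,4,7,6,6
Polygonum aviculare s. l.,7,6,4,4,6,6
Potentilla supina,8,7,5,7,6,6
Pulicaria vulgaris,8,7,5,7,6,7
Radiola linoides,8,6,2,7,3,2
Ranunculus sardous,8,6,3,7,6,6
Riccia cavernosa,8,6,5,8,6,6
Riccia glauca,7,5,3,6,5,5
Riccia sorocarpa,7,5,4,5,5,4
Rorippa palustris,8,5,,8,6,7
Rumex acetosella,7,5,3,4,2,2
Rumex maritimus,8,6,5,8,7,9
Sagina nodosa,8,5,3,7,6,3
Sagina procumbens,7,5,3,6,5,5
Schoenoplectus supinus,8,8,6,9,6,5
Scleranthus annuus,7,5,3,4,2,3
Spergula arvensis,7,5,4,5,3,4
Spergularia rubra,8,5,4,5,3,4
Stellaria alsine,6,5,3,8,4,4
Veronica peregrina,7,6,5,7,5,5
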