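# Published relevé counts of the identified vegetation units (classification
# of the national vegetation-plot database; counts after geographic
# stratification, 903 relevés analysed in total).
total_releves: 903
class_level_only: 197
alliance_level_only: 157
clusters:
  - cluster: A
    alliance: Eleocharition soloniensis
    releves: 272
    units:
      - {name: Polygono-Eleocharitetum ovatae, rank: association, releves: 129}
      - {name: Cypero fusci-Limoselletum aquaticae, rank: association, releves: 127}
      - {name: Cyperetum micheliani, rank: association, releves: 4}
      - {name: Community with Coleanthus subtilis, rank: community, releves: 12}
  - cluster: B
    alliance: Verbenion supinae
    releves: 46
    units:
      - {name: Veronico anagalloidis-Lythretum hyssopifoliae, rank: association, releves: 3}
      - {name: Cyperetum flavescentis, rank: association, releves: 8}
      - {name: Pulicario vulgaris-Menthetum pulegii, rank: association, releves: 19}
      - {name: Eleocharito-Schoenoplectetum supini, rank: association, releves: 16}
  - cluster: C
    alliance: Radiolion linoidis
    releves: 223
    units:
      - {name: Stellario uliginosae-Isolepidetum setaceae, rank: association, releves: 20}
      - {name: Centunculo minimi-Anthoceretum punctati, rank: association, releves: 90}
      - {name: Hyperico humifusi-Spergularietum rubrae, rank: association, releves: 42}
      - {name: Panico-Illecebretum verticillati, rank: association, releves: 47}
      - {name: Cerastio dubii-Ranunculetum sardoi, rank: association, releves: 9}
      - {name: Community with Montia arvensis, rank: community, releves: 15}
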