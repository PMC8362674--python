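# Species groups used by the packaged formal definitions.
#
# Kinds:
#   TC  - total-cover group (#TC): condition uses the combined cover of all
#         members present, combined under the independence formula.
#   SC  - single-cover group (#SC): condition uses the highest cover reached
#         by any single member.
#   SOC - sociological group (###): treated as "present" when at least
#         min_members members occur (default: half the members, rounded up).
#
# The class group is the preselected list of 63 diagnostic species of the
# ephemeral dwarf-wetland class (Isoeto-Nanojuncetea); the three alliance
# groups and the eight sociological groups follow the published group lists.
groups:
  - name: Isoeto-Nanojuncetea
    kind: TC
    members:
      - Anagallis minima
      - Anthoceros punctatus s. l.
      - Cardamine parviflora
      - Carex bohemica
      - Centaurium pulchellum
      - Cerastium dubium
      - Coleanthus subtilis
      - Crassula aquatica
      - Cyperus fuscus
      - Cyperus michelianus
      - Cyperus esculentus
      - Elatine alsinastrum
      - Elatine hexandra
      - Elatine hydropiper
      - Elatine triandra
      - Eleocharis acicularis
      - Eleocharis ovata
      - Fossombronia wondraczekii
      - Gnaphalium uliginosum
      - Gratiola neglecta
      - Gypsophila muralis
      - Hypericum humifusum
      - Illecebrum verticillatum
      - Isolepis setacea
      - Juncus bufonius
      - Juncus capitatus
      - Juncus ranarius
      - Juncus tenageia
      - Laphangium luteoalbum
      - Limosella aquatica
      - Lindernia dubia
      - Lindernia procumbens
      - Lythrum hyssopifolia
      - Lythrum portula
      - Mentha pulegium
      - Montia arvensis
      - Myosurus minimus
      - Phaeoceros laevis
      - Plantago major subsp. intermedia
      - Potentilla supina
      - Pulicaria vulgaris
      - Cyperus flavescens
      - Radiola linoides
      - Ranunculus sardous
      - Riccia beyrichiana
      - Riccia bifurca
      - Riccia canaliculata
      - Riccia cavernosa
      - Riccia ciliifera
      - Riccia crystallina
      - Riccia duplex
      - Riccia huebeneriana
      - Riccia warnstorfii
      - Riccia glauca
      - Riccia sorocarpa
      - Sagina apetala
      - Sagina nodosa
      - Schoenoplectus supinus
      - Spergularia echinosperma
      - Spergularia rubra
      - Veronica anagalloides
      - Veronica catenata
      - Veronica peregrina
  - name: Eleocharition soloniensis
    kind: TC
    members:
      - Carex bohemica
      - Coleanthus subtilis
      - Crassula aquatica
      - Cyperus fuscus
      - Cyperus michelianus
      - Elatine hexandra
      - Elatine hydropiper
      - Elatine triandra
      - Eleocharis ovata
      - Limosella aquatica
      - Lindernia dubia
      - Lindernia procumbens
      - Potentilla supina
      - Riccia canaliculata
      - Riccia cavernosa
  - name: Radiolion linoidis
    kind: TC
    members:
      - Anagallis minima
      - Anthoceros punctatus s. l.
      - Fossombronia wondraczekii
      - Gypsophila muralis
      - Hypericum humifusum
      - Illecebrum verticillatum
      - Isolepis setacea
      - Juncus capitatus
      - Montia arvensis
      - Phaeoceros laevis
      - Radiola linoides
      - Ranunculus sardous
      - Spergularia rubra
  - name: Verbenion supinae
    kind: TC
    members:
      - Elatine alsinastrum
      - Juncus ranarius
      - Lythrum hyssopifolia
      - Mentha pulegium
      - Pulicaria vulgaris
      - Cyperus flavescens
      - Schoenoplectus supinus
  - name: Cyperus fuscus group
    kind: SOC
    members:
      - Cyperus fuscus
      - Potentilla supina
      - Limosella aquatica
  - name: Elatine alsinastrum group
    kind: SOC
    members:
      - Alisma lanceolatum
      - Elatine alsinastrum
      - Schoenoplectus supinus
  - name: Elatine hexandra group
    kind: SOC
    members:
      - Elatine hexandra
      - Elatine triandra
      - Elatine hydropiper
  - name: Eleocharis ovata group
    kind: SOC
    members:
      - Carex bohemica
      - Eleocharis ovata
      - Lindernia procumbens
  - name: Myosurus minimus group
    kind: SOC
    members:
      - Bryum ruderale
      - Myosurus minimus
      - Ranunculus sardous
  - name: Centunculus minimus group
    kind: SOC
    members:
      - Anthoceros punctatus s. l.
      - Anagallis minima
      - Juncus capitatus
      - Radiola linoides
  - name: Gypsophila muralis group
    kind: SOC
    members:
      - Gypsophila muralis
      - Laphangium luteoalbum
      - Spergularia rubra
  - name: Isolepis setacea group
    kind: SOC
    members:
      - Isolepis setacea
      - Juncus tenageia
      - Stellaria alsine
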