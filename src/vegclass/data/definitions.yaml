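# Reconstructed formal-definition set (expert system) for the ephemeral
# dwarf-wetland vegetation class and its three Central European alliances.
#
# RECONSTRUCTED: the published expert-system file is not redistributed here;
# these formulas reproduce its documented structure — #TC total-cover
# thresholds for the class and alliances, and sociological species groups or
# a 25% single-species dominance clause (tied to the alliance total-cover
# group) for the associations. Every threshold is editable in this file.
groups_file: species_groups.yaml
syntaxa:
  - name: Isoeto-Nanojuncetea
    rank: class
    formula: "TC(Isoeto-Nanojuncetea) > 25"

  - name: Eleocharition soloniensis
    rank: alliance
    parent: Isoeto-Nanojuncetea
    formula: "TC(Eleocharition soloniensis) > 25"
  - name: Verbenion supinae
    rank: alliance
    parent: Isoeto-Nanojuncetea
    formula: "TC(Verbenion supinae) > 25"
  - name: Radiolion linoidis
    rank: alliance
    parent: Isoeto-Nanojuncetea
    formula: "TC(Radiolion linoidis) > 25"

  # --- Eleocharition soloniensis -------------------------------------------
  - name: Polygono-Eleocharitetum ovatae
    rank: association
    parent: Eleocharition soloniensis
    formula: "(SOC(Eleocharis ovata group) OR SOC(Elatine hexandra group)) AND TC(Eleocharition soloniensis) > 25"
  - name: Cypero fusci-Limoselletum aquaticae
    rank: association
    parent: Eleocharition soloniensis
    formula: "SOC(Cyperus fuscus group) AND TC(Eleocharition soloniensis) > 25 AND NOT COV(Cyperus michelianus) > 25"
  - name: Cyperetum micheliani
    rank: association
    parent: Eleocharition soloniensis
    formula: "COV(Cyperus michelianus) > 25 AND TC(Eleocharition soloniensis) > 25"
  - name: Community with Coleanthus subtilis
    rank: association
    parent: Eleocharition soloniensis
    formula: "COV(Coleanthus subtilis) > 25 AND TC(Eleocharition soloniensis) > 25"

  # --- Verbenion supinae ----------------------------------------------------
  - name: Veronico anagalloidis-Lythretum hyssopifoliae
    rank: association
    parent: Verbenion supinae
    formula: "COV(Juncus ranarius) > 25 AND TC(Verbenion supinae) > 25"
  - name: Cyperetum flavescentis
    rank: association
    parent: Verbenion supinae
    formula: "COV(Cyperus flavescens) > 25 AND TC(Verbenion supinae) > 25"
  - name: Pulicario vulgaris-Menthetum pulegii
    rank: association
    parent: Verbenion supinae
    formula: "COV(Pulicaria vulgaris) > 25 AND TC(Verbenion supinae) > 25"
  - name: Eleocharito-Schoenoplectetum supini
    rank: association
    parent: Verbenion supinae
    formula: "SOC(Elatine alsinastrum group) AND TC(Verbenion supinae) > 25"

  # --- Radiolion linoidis ---------------------------------------------------
  - name: Stellario uliginosae-Isolepidetum setaceae
    rank: association
    parent: Radiolion linoidis
    formula: "SOC(Isolepis setacea group) AND TC(Radiolion linoidis) > 25"
  - name: Centunculo minimi-Anthoceretum punctati
    rank: association
    parent: Radiolion linoidis
    formula: "SOC(Centunculus minimus group) AND TC(Radiolion linoidis) > 25"
  - name: Hyperico humifusi-Spergularietum rubrae
    rank: association
    parent: Radiolion linoidis
    formula: "SOC(Gypsophila muralis group) AND TC(Radiolion linoidis) > 25"
  - name: Panico-Illecebretum verticillati
    rank: association
    parent: Radiolion linoidis
    formula: "COV(Illecebrum verticillatum) > 25 AND TC(Radiolion linoidis) > 25"
  - name: Cerastio dubii-Ranunculetum sardoi
    rank: association
    parent: Radiolion linoidis
    formula: "SOC(Myosurus minimus group) AND TC(Radiolion linoidis) > 25"
  - name: Community with Montia arvensis
    rank: association
    parent: Radiolion linoidis
    formula: "COV(Montia arvensis) > 25 AND TC(Radiolion linoidis) > 25"
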