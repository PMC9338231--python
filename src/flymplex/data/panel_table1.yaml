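# The published five-species tephritid multiplex panel (opsin Rh4 region).
# Primer concentrations are the per-primer µM in the 25 µl multiplex reaction.
# The quilicii pair sits in an intergenic region just outside the opsin Rh4
# coding domain and is known to cross-amplify in related species, hence the
# cross_amplification_risk flag driving the duplex tie-break rule.
name: table1
entries:
  - species: capitata
    forward: {name: Opsin4_capitata_F, seq: GCTAAAGCCATAACAATTCAG}
    reverse: {name: Opsin4_capitata_R, seq: CAGACTGTTCTTTTGGGC}
    expected_size: 327
    conc_uM: 0.24
    cross_amplification_risk: false
  - species: cosyra
    forward: {name: Opsin4_cosyra_F, seq: GCTGTGACTTTGTTACAG}
    reverse: {name: Opsin4_cosyra_R, seq: GCATACTTGAATCTCAATCGAA}
    expected_size: 183
    conc_uM: 0.32
    cross_amplification_risk: false
  - species: quilicii
    forward: {name: Opsin4_quilicii_F, seq: GCGTTCTGTTTTTAATCACTCA}
    reverse: {name: Opsin4_quilicii_R, seq: CATTTAATGTTTCAGAAGTGCT}
    expected_size: 128
    conc_uM: 0.32
    cross_amplification_risk: true
  - species: rosa
    forward: {name: Opsin4_rosa_F, seq: ATTGCTACAACTTTGTCGC}
    reverse: {name: Opsin4_rosa_R, seq: GCAGTAATACTGCGAATCATC}
    expected_size: 249
    conc_uM: 0.64
    cross_amplification_risk: false
  - species: dorsalis
    forward: {name: Opsin4_dorsalis_F, seq: TAGCACAATTATTTAGCGGG}
    reverse: {name: Opsin4_dorsalis_R, seq: ATTACCGTCAGCGATCAG}
    expected_size: 676
    conc_uM: 0.64
    cross_amplification_risk: false
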