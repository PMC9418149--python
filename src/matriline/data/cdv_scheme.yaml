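# Chicken control-region haplogroup classification scheme around the
# reclassified macrohaplogroup CDV, in the standard A-I/V-Z nomenclature.
#
# Each node lists the diagnostic substitution motifs on its branch beyond
# its parent; a sample must carry the full cumulative root-to-node motif
# path to be assigned to a node. Cumulative published sets encoded here:
#   V   = {A281G, T355C, C363T}
#   V2  = V + {C228T, A237G, C391T}
#   D1b = {A281G, C296T, T306C, A342G, G686A}
# The shared token A281G sits on the macrohaplogroup CDV branch.
#
# Nodes marked source: synthetic-placeholder carry invented motifs (their
# defining tables are published only in supplementary material); replace
# them with a real scheme table for real-data work. Positions are 1-based
# on the 1232-bp control-region frame.
- name: ROOT
  parent: null
  motifs: []
- name: A
  parent: ROOT
  motifs: [C167T]
  source: synthetic-placeholder
- name: B
  parent: ROOT
  motifs: [A912G]
  source: synthetic-placeholder
- name: E
  parent: ROOT
  motifs: [C447T, A510G]
  source: synthetic-placeholder
- name: F
  parent: ROOT
  motifs: [T727C]
  source: synthetic-placeholder
- name: CDV
  parent: ROOT
  motifs: [A281G]
- name: C
  parent: CDV
  motifs: [G563A]
  source: synthetic-placeholder
- name: V
  parent: CDV
  motifs: [T355C, C363T]
- name: V1
  parent: V
  motifs: [A415G]
  source: synthetic-placeholder
- name: V2
  parent: V
  motifs: [C228T, A237G, C391T]
- name: D
  parent: CDV
  motifs: [C296T]
- name: D1
  parent: D
  motifs: [T306C]
- name: D1a
  parent: D1
  motifs: [C775T]
  source: synthetic-placeholder
- name: D1b
  parent: D1
  motifs: [A342G, G686A]
- name: D2
  parent: D
  motifs: [T893C, A988G]
  source: synthetic-placeholder
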