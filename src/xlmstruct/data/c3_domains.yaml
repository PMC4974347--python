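# Domain annotation for mature human complement C3 (1-based mature numbering:
# beta-chain 1-645, alpha-chain 650-1641; residues 646-649 are excised during
# maturation and belong to no chain).
#
# NOTE: the exact domain boundaries are RECONSTRUCTED from the C3 crystal
# structure literature; they are editable and are only used for labelling and
# for the default rigid-body partition. Every boundary is consistent with the
# residue-domain pairings used throughout this package's documentation
# (44/75 in MG1, 203 in MG2, 241/267 in MG3, 650/670 in ANA, 727 in the
# alpha-chain N-terminal segment, 851/882 in MG7, 1049/1181/1195 in TED,
# 1293 in CUB, 1346/1409 in MG8, 1475/1479/1491 in the anchor,
# 1539/1567/1573 in C345C).
protein_id: C3_human_mature
chains:
  - [beta, 1, 645]
  - [alpha, 650, 1641]
domains:
  MG1: [[1, 104]]
  MG2: [[105, 209]]
  MG3: [[210, 328]]
  MG4: [[329, 425]]
  MG5: [[426, 534]]
  MG6: [[535, 577], [746, 806]]
  LNK: [[578, 645]]
  ANA: [[650, 726]]
  α-NT: [[727, 745]]
  MG7: [[807, 911]]
  CUB: [[912, 962], [1269, 1330]]
  TED: [[963, 1268]]
  MG8: [[1331, 1474]]
  anchor: [[1475, 1495]]
  C345C: [[1496, 1641]]
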