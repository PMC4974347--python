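# Default rigid-body partition for coarse-grained modeling of C3 / C3b /
# C3(H2O). RECONSTRUCTED: the published figure showing the partition is not
# accompanied by residue ranges, so these ranges mirror the shipped domain
# annotation (c3_domains.yaml).
#
# The core body "MG1-6_a'NT" holds the beta-chain key-ring (MG1-MG6 + LNK)
# together with the alpha-chain N-terminal segment and the alpha half of MG6;
# it is the superposition target for all ensemble analysis and is held fixed
# during sampling. The anchor (1475-1495) is a flexible string, as are any
# residues not listed under a rigid body.
protein_id: C3_human_mature
core: MG1-6_a'NT
rigid_bodies:
  MG1-6_a'NT: [[1, 645], [727, 806]]
  ANA: [[650, 726]]
  MG7: [[807, 911]]
  CUB: [[912, 962], [1269, 1330]]
  TED: [[963, 1268]]
  MG8: [[1331, 1474]]
  C345C: [[1496, 1641]]
flexible:
  anchor: [[1475, 1495]]
disulfides:
  - [851, 1491]
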