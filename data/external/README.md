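# External inputs (not redistributed)

Some acceptance checks reproduce published numbers from inputs that cannot
ship with this repository (crystal structures from the PDB and the
quantitation / restraint tables from the study's supplementary material).
Place the following files here to enable them; the corresponding tests in
`tests/test_acceptance.py` fail with a pointer to this file when they are
absent.

| file | content | format |
| --- | --- | --- |
| `2A73.pdb` | crystal structure of complement C3 | PDB, from rcsb.org |
| `2I07.pdb` | crystal structure of complement C3b | PDB, from rcsb.org |
| `table_s2_c3.tsv` | peptide-pair quantitation of the C3(H2O)-vs-C3 comparison | package quant-table TSV (see below) |
| `table_s2_c3b.tsv` | peptide-pair quantitation of the C3(H2O)-vs-C3b comparison | same |
| `table_s3_c3.tsv` | 82 modeling restraints for C3 | TSV: res_a, res_b, class |
| `table_s3_c3b.tsv` | 75 modeling restraints for C3b | TSV: res_a, res_b, class |
| `table_s3_c3h2o.tsv` | 85 modeling restraints for C3(H2O) | TSV: res_a, res_b, class |

Quant-table TSV columns (one row per peptide pair per sample):
`sample_id, experiment_id, label_orientation, peptide_pair_id, res_a, res_b,
area_light, area_heavy, detection`, where `label_orientation` names the
condition carrying the heavy linker (`condition1` is C3 or C3b,
`condition2` is the shared reference C3(H2O)) and `detection` is `doublet`,
`singlet_condition1` or `singlet_condition2`. Restraint `class` is
`consistent` (identified in all experiments) or `single` (identified once).
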