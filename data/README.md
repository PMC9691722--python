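# Optional external data

Everything in the package runs on synthetic data; the files below are only
needed for the worked examples that reproduce published structure and
library numbers.  They are not redistributed here — place them in this
directory yourself:

* `7rk7.cif` (or `7rk7.pdb`) — the TIL1383I–Tyr370D/HLA-A2 complex,
  from https://www.rcsb.org/structure/7RK7
* `5jzi.cif` (or `5jzi.pdb`) — the canonically docking HCV1406–NS3/HLA-A2
  complex, from https://www.rcsb.org/structure/5JZI
* `library_dg.csv` — measured binding free energies of the 140-member
  positional-scanning library (columns `position`, `amino_acid`,
  `dg_kcal_mol`; wild-type replicates as rows with position 0), derived
  from the SPR source data deposited at https://zenodo.org/record/7259584

Chain annotations for the structures can be overridden with
`<name>_annotation.json` files of the form

```json
{"tcr_alpha": "D", "tcr_beta": "E", "mhc_heavy": "A", "peptide": "C",
 "v_domain_ranges": {"D": [1, 115], "E": [1, 116]}, "groove_range": [1, 180]}
```
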