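{
 "comment": "RNA/RNA Watson-Crick nearest-neighbor stack free energies at 37 C, kcal/mol. Key XY/ZW: top strand 5'-XY-3' stacked on bottom strand 3'-ZW-5' (X pairs Z, Y pairs W). Values from the Turner-lab parameter set (Xia et al. 1998, Biochemistry 37:14719). init_penalty is the duplex initiation term from the same set.",
 "init_penalty": 4.09,
 "stack_energies": {
  "AA/UU": -0.93,
  "AC/UG": -2.24,
  "AG/UC": -2.08,
  "AU/UA": -1.1,
  "CA/GU": -2.11,
  "CC/GG": -3.26,
  "CG/GC": -2.36,
  "CU/GA": -2.08,
  "GA/CU": -2.35,
  "GC/CG": -3.42,
  "GG/CC": -3.26,
  "GU/CA": -2.24,
  "UA/AU": -1.33,
  "UC/AG": -2.35,
  "UG/AC": -2.11,
  "UU/AA": -0.93
 }
}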