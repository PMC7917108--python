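{
 "bulge_initiation_dg37": {
  "1": 3.8,
  "2": 2.8,
  "3": 3.2,
  "4": 3.6,
  "5": 4.0,
  "6": 4.4
 },
 "description": "RNA nearest-neighbor helix stack free energies dG37 (kcal/mol), Turner 2004 parameter set including G-U wobble pairs. Key 'X1X2/Y1Y2': top strand 5'->3' dinucleotide X1X2 stacked on bottom strand Y1Y2 written 3'->5' (Y1 pairs X1, Y2 pairs X2).",
 "interior_mismatch_penalty_dg37": 1.1,
 "stack_dg37": {
  "AA/UU": -0.9,
  "AC/UG": -2.2,
  "AG/UC": -2.1,
  "AG/UU": -0.6,
  "AU/UA": -1.1,
  "AU/UG": -1.4,
  "CA/GU": -2.1,
  "CC/GG": -3.3,
  "CG/GC": -2.4,
  "CG/GU": -1.4,
  "CU/GA": -2.1,
  "CU/GG": -2.1,
  "GA/CU": -2.4,
  "GA/UU": -1.3,
  "GC/CG": -3.4,
  "GC/UG": -2.5,
  "GG/CC": -3.3,
  "GG/CU": -1.5,
  "GG/UC": -2.1,
  "GG/UU": -0.5,
  "GU/CA": -2.2,
  "GU/CG": -2.5,
  "GU/UA": -1.4,
  "GU/UG": 1.3,
  "UA/AU": -1.3,
  "UA/GU": -1.0,
  "UC/AG": -2.4,
  "UC/GG": -1.5,
  "UG/AC": -2.1,
  "UG/AU": -1.0,
  "UG/GC": -1.4,
  "UG/GU": 0.3,
  "UU/AA": -0.9,
  "UU/AG": -1.3,
  "UU/GA": -0.6,
  "UU/GG": -0.5
 },
 "temperature_c": 37,
 "units": "kcal/mol"
}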