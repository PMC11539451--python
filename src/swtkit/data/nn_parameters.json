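{
  "name": "turner-style-rna-37C",
  "provenance": "Turner-style RNA nearest-neighbor free energies at 37 C (kcal/mol). Watson-Crick/Watson-Crick stack values follow the Turner 2004 set; wobble-containing stacks are approximate published values; hairpin/bulge/internal loop initiation tables are simplified (no sequence-dependent mismatch, dangle, coaxial or terminal-AU terms). Loop penalties beyond the tabulated sizes are extrapolated as dG(n) = dG(n_max) + 1.75*RT*ln(n/n_max).",
  "temperature_K": 310.15,
  "stack_dG": {
    "AU.AU": -0.93, "AU.UA": -1.10, "AU.CG": -2.24, "AU.GC": -2.08, "AU.GU": -0.55, "AU.UG": -1.36,
    "UA.AU": -1.33, "UA.UA": -0.93, "UA.CG": -2.35, "UA.GC": -2.11, "UA.GU": -1.00, "UA.UG": -1.27,
    "CG.AU": -2.11, "CG.UA": -2.08, "CG.CG": -3.26, "CG.GC": -2.36, "CG.GU": -1.41, "CG.UG": -2.11,
    "GC.AU": -2.35, "GC.UA": -2.24, "GC.CG": -3.42, "GC.GC": -3.26, "GC.GU": -2.51, "GC.UG": -1.53,
    "GU.AU": -1.27, "GU.UA": -1.36, "GU.CG": -1.53, "GU.GC": -2.11, "GU.GU": -0.50, "GU.UG": 1.29,
    "UG.AU": -1.00, "UG.UA": -0.55, "UG.CG": -2.51, "UG.GC": -1.41, "UG.GU": 0.30, "UG.UG": -0.50
  },
  "hairpin_loop_dG": {"3": 5.4, "4": 5.6, "5": 5.7, "6": 5.4, "7": 6.0, "8": 5.5, "9": 6.4},
  "bulge_dG": {"1": 3.8, "2": 2.8, "3": 3.2, "4": 3.6, "5": 4.0, "6": 4.4},
  "internal_loop_dG": {"2": 1.7, "3": 1.8, "4": 2.0, "5": 2.2, "6": 2.5},
  "multiloop_dG": {"closing": 3.4, "branch": 0.4, "unpaired": 0.0},
  "duplex_init_dG": 4.09,
  "loop_extrapolation_coeff": 1.75,
  "max_interior_size": 30,
  "min_hairpin_loop": 3
}
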