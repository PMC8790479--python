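# Expanded newborn-screening marker panel: 43 measured channels (11 amino acids,
# one ketone, 31 acylcarnitine species, some reported as combined channels by the
# non-derivatized MS/MS kit) plus 31 derived ratios.  Concentrations in umol/L;
# ratios dimensionless.  low/high bound the laboratory reference interval.
markers:
  - {name: "C0", kind: raw_analyte, low: 9, high: 50}
  - {name: "C2", kind: raw_analyte, low: 3, high: 48}
  - {name: "C3", kind: raw_analyte, low: 0.35, high: 4.0}
  - {name: "C3DC + C4OH", kind: combined_channel, low: 0.03, high: 0.4}
  - {name: "C4", kind: raw_analyte, low: 0.1, high: 0.5}
  - {name: "C4DC + C5OH", kind: combined_channel, low: 0.07, high: 0.4}
  - {name: "C5", kind: raw_analyte, low: 0.03, high: 0.3}
  - {name: "C5:1", kind: raw_analyte, low: 0, high: 0.03}
  - {name: "C5DC + C6OH", kind: combined_channel, low: 0.03, high: 0.25}
  - {name: "C6", kind: raw_analyte, low: 0.01, high: 0.11}
  - {name: "C6DC", kind: raw_analyte, low: 0.03, high: 0.27}
  - {name: "C8", kind: raw_analyte, low: 0.02, high: 0.2}
  - {name: "C8:1", kind: raw_analyte, low: 0.03, high: 0.45}
  - {name: "C10:1", kind: raw_analyte, low: 0.02, high: 0.17}
  - {name: "C10", kind: raw_analyte, low: 0.02, high: 0.3}
  - {name: "C10:2", kind: raw_analyte, low: 0, high: 0.15}
  - {name: "C12", kind: raw_analyte, low: 0.02, high: 0.35}
  - {name: "C12:1", kind: raw_analyte, low: 0.01, high: 0.37}
  - {name: "C14", kind: raw_analyte, low: 0.04, high: 0.45}
  - {name: "C14:1", kind: raw_analyte, low: 0.02, high: 0.35}
  - {name: "C14:2", kind: raw_analyte, low: 0, high: 0.05}
  - {name: "C14OH", kind: raw_analyte, low: 0, high: 0.05}
  - {name: "C16", kind: raw_analyte, low: 0.5, high: 6.86}
  - {name: "C16:1", kind: raw_analyte, low: 0.02, high: 0.5}
  - {name: "C16OH", kind: raw_analyte, low: 0, high: 0.06}
  - {name: "C16:1OH", kind: raw_analyte, low: 0.01, high: 0.08}
  - {name: "C18", kind: raw_analyte, low: 0.24, high: 2}
  - {name: "C18:1", kind: raw_analyte, low: 0.38, high: 3}
  - {name: "C18:2", kind: raw_analyte, low: 0.05, high: 0.6}
  - {name: "C18OH", kind: raw_analyte, low: 0, high: 0.03}
  - {name: "C18:1OH", kind: raw_analyte, low: 0, high: 0.06}
  - {name: "ALA", kind: raw_analyte, low: 125, high: 650}
  - {name: "ARG", kind: raw_analyte, low: 1, high: 45}
  - {name: "CIT", kind: raw_analyte, low: 5.5, high: 26}
  - {name: "GLY", kind: raw_analyte, low: 190, high: 1000}
  - {name: "LEU + ILE + PRO-OH", kind: combined_channel, low: 50, high: 260}
  - {name: "MET", kind: raw_analyte, low: 6.5, high: 40}
  - {name: "ORN", kind: raw_analyte, low: 30, high: 250}
  - {name: "PHE", kind: raw_analyte, low: 23, high: 100}
  - {name: "PRO", kind: raw_analyte, low: 75, high: 420}
  - {name: "SA", kind: raw_analyte, low: 0, high: 1.6}
  - {name: "TYR", kind: raw_analyte, low: 30, high: 250}
  - {name: "VAL", kind: raw_analyte, low: 40, high: 230}
  - {name: "ARG/PHE", kind: ratio, numerator: ["ARG"], denominator: ["PHE"], low: 0.02, high: 0.7}
  - {name: "(C4DC + C5OH)/C0", kind: ratio, numerator: ["C4DC + C5OH"], denominator: ["C0"], low: 0, high: 0.03}
  - {name: "MET/PHE", kind: ratio, numerator: ["MET"], denominator: ["PHE"], low: 0.1, high: 0.6}
  - {name: "MET/CIT", kind: ratio, numerator: ["MET"], denominator: ["CIT"], low: 0.51, high: 4}
  - {name: "ORN/CIT", kind: ratio, numerator: ["ORN"], denominator: ["CIT"], low: 2.5, high: 22}
  - {name: "ARG/ORN", kind: ratio, numerator: ["ARG"], denominator: ["ORN"], low: 0.01, high: 0.4}
  - {name: "ALA/CIT", kind: ratio, numerator: ["ALA"], denominator: ["CIT"], low: 9.5, high: 65}
  - {name: "CIT/PHE", kind: ratio, numerator: ["CIT"], denominator: ["PHE"], low: 0.1, high: 0.7}
  - {name: "PHE/TYR", kind: ratio, numerator: ["PHE"], denominator: ["TYR"], low: 0.2, high: 1.4}
  - {name: "SA/PHE", kind: ratio, numerator: ["SA"], denominator: ["PHE"], low: 0, high: 0.04}
  - {name: "TYR/PHE", kind: ratio, numerator: ["TYR"], denominator: ["PHE"], low: 0.6, high: 7}
  - {name: "(LEU + ILE + PRO-OH)/PHE", kind: ratio, numerator: ["LEU + ILE + PRO-OH"], denominator: ["PHE"], low: 1.15, high: 5.2}
  - {name: "(LEU + ILE + PRO-OH)/TYR", kind: ratio, numerator: ["LEU + ILE + PRO-OH"], denominator: ["TYR"], low: 0.5, high: 4.2}
  - {name: "C0/(C16 + C18)", kind: ratio, numerator: ["C0"], denominator: ["C16", "C18"], low: 1.8, high: 30}
  - {name: "C3/C0", kind: ratio, numerator: ["C3"], denominator: ["C0"], low: 0.01, high: 0.2}
  - {name: "C3/C2", kind: ratio, numerator: ["C3"], denominator: ["C2"], low: 0.03, high: 0.2}
  - {name: "C3/MET", kind: ratio, numerator: ["C3"], denominator: ["MET"], low: 0.02, high: 0.3}
  - {name: "C4/C2", kind: ratio, numerator: ["C4"], denominator: ["C2"], low: 0, high: 0.04}
  - {name: "C4/C3", kind: ratio, numerator: ["C4"], denominator: ["C3"], low: 0.04, high: 0.45}
  - {name: "C5/C0", kind: ratio, numerator: ["C5"], denominator: ["C0"], low: 0, high: 0.02}
  - {name: "C8/C2", kind: ratio, numerator: ["C8"], denominator: ["C2"], low: 0, high: 0.01}
  - {name: "C8/C10", kind: ratio, numerator: ["C8"], denominator: ["C10"], low: 0.3, high: 1.5}
  - {name: "C14:1/C2", kind: ratio, numerator: ["C14:1"], denominator: ["C2"], low: 0, high: 0.02}
  - {name: "C14:1/C16", kind: ratio, numerator: ["C14:1"], denominator: ["C16"], low: 0.01, high: 0.1}
  - {name: "C16OH/C16", kind: ratio, numerator: ["C16OH"], denominator: ["C16"], low: 0, high: 0.02}
  - {name: "(C16 + C18:1)/C2", kind: ratio, numerator: ["C16", "C18:1"], denominator: ["C2"], low: 0.12, high: 0.55}
  - {name: "(C3DC + C4OH)/C10", kind: ratio, numerator: ["C3DC + C4OH"], denominator: ["C10"], low: 0.35, high: 4.33}
  - {name: "(C5DC + C6OH)/(C3DC + C4OH)", kind: ratio, numerator: ["C5DC + C6OH"], denominator: ["C3DC + C4OH"], low: 0.3, high: 2}
  - {name: "(C5DC + C6OH)/(C4DC + C5OH)", kind: ratio, numerator: ["C5DC + C6OH"], denominator: ["C4DC + C5OH"], low: 0.15, high: 1.6}
  - {name: "(C0 + C2 + C3 + C16 + C18:1 + C18)/CIT", kind: ratio, numerator: ["C0", "C2", "C3", "C16", "C18:1", "C18"], denominator: ["CIT"], low: 1.3, high: 12}
  - {name: "(C4DC + C5OH)/C8", kind: ratio, numerator: ["C4DC + C5OH"], denominator: ["C8"], low: 1, high: 12}
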