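{
  "flags": [
    {
      "id": "add_c2_hydroxyl_rounding",
      "reaction": "add_c2_hydroxyl",
      "printed_delta_g": -1.3,
      "tabulated_delta_g": -1.4,
      "note": "The source text prints dG = -1.3 for this step while the tabulated G_rel values (-12.8 and -11.4) give -1.4; the unrounded upstream values evidently differ from the printed ones by <= 0.1. Both numbers are recorded; the discrepancy is flagged, not resolved."
    },
    {
      "id": "aldol_c3_branch21_arithmetic",
      "reaction": "aldol_c3_branch21",
      "printed_delta_g": -7.3,
      "tabulated_delta_g": -7.0,
      "note": "The source text prints dG = -21.8 - (-17.4 + 2.6) = -7.3, but that arithmetic evaluates to -7.0. The operands are stored; the map therefore computes -7.0."
    },
    {
      "id": "c2_aldol_accounting",
      "reaction": "aldol_c2_keep",
      "note": "The printed overall dG (-4.6) and uncatalyzed barrier (+32.1) for the C2+C1 aldol are each consistent with the tabulated values only if the C1 reactant's G_rel (+2.6) is omitted from the reactant sum; the tabulated values give -7.2 and +29.5. The printed pair is not stored as energies."
    }
  ],
  "gaps": [
    "Species 5 (S-attack adduct of the C2 aldehyde) is described qualitatively only; no value is available in the running text, so it is omitted.",
    "Species 19/19e (dihydroxyacetone adduct and enediol), 25, 27, 28, 29 ring forms, the C2 enol adducts 7ec/7et, the C3 enols, and the non-lyxose open-chain 2,4 / non-xylose 2,5 pentose adducts carry figure-only values that are not available in the transcription source; they are omitted and the trioses group therefore contains only the species with recorded energies.",
    "Values for 11-15 are under-determined individually: only sums are printed. One free split parameter was fixed arbitrarily (see species provenance 'assigned'); every printed reaction energy is reproduced independently of the split."
  ],
  "provenance_legend": {
    "text": "printed directly in the running text",
    "text-derived": "one arithmetic step from printed values",
    "assigned": "consistent split of an under-determined printed sum",
    "approx": "printed only as an approximate value"
  }
}
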