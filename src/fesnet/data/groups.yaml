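# Isomer/adduct groups for speciation analysis.
# members must be mutually balanceable using only the exchange species.
c2_adducts:
  label: "glycolaldehyde and its bisulfite adducts"
  members: ["4", "6", "7", "8"]
  exchange: ["H2O", "H2SO3"]
pair_7_8:
  label: "aldehyde adduct vs hydrate"
  members: ["7", "8"]
  exchange: ["H2O"]
trioses:
  label: "C3 aldoses and bisulfite adducts"
  members: ["16", "17", "18"]
  exchange: ["H2O", "H2SO3"]
c4_ketose_adducts:
  label: "C4 ketose and bisulfite adducts"
  members: ["20", "23", "24"]
  exchange: ["H2O", "H2SO3"]
c4_aldose_adducts:
  label: "C4 aldoses with and without bisulfite"
  members: ["26thr", "26ery", "29thr", "29ery"]
  exchange: ["H2O", "H2SO3"]
pentopyranose_24:
  label: "2,4-pentopyranose diastereomers"
  members: ["31rib", "31ara"]
  exchange: []
pentose_25:
  label: "2,5-pentose adducts"
  members: ["32xyl", "33rib"]
  exchange: []
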