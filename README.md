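# fesnet

Free-energy maps of aqueous C/H/O/S reaction networks.

`fesnet` implements a reusable pipeline around the "relative free energy"
bookkeeping used for sugar/bisulfite reaction networks:

- **thermo** — assemble solution-phase free energies from component terms
  (electronic + ZPE, 298.15 K enthalpy correction, a configurable fraction
  of the gas-phase entropy — default one half — and an implicit-solvation
  term), and place species on a common scale (`G_rel`) defined as the ΔG of
  an automatically balanced formation reaction from the reference basis
  CO₂ / H₂ / H₂O / H₂SO₃ (each at `G_rel = 0`). Stoichiometry is solved in
  exact rational arithmetic.
- **network** — reactions as reactant/product multisets with optional
  transition-state links; ΔG = G_rel(products) − G_rel(reactants);
  forward/reverse activation barriers with explicit "submerged barrier"
  and typed "no barrier" results; a Hess-cycle audit over the complex
  graph (all cycle residuals vanish for a state-function-consistent map);
  ΔΔG/ΔΔG‡ ledgers across matched reaction variants.
- **speciation** — Boltzmann populations and stability rankings of
  isomer/adduct groups (closed groups, degeneracy-aware, members must be
  mutually balanceable via exchange species such as water).
- **kinetics** — Eyring conversion of barriers to mass-action rate
  constants (`k = k_BT/h · exp(−ΔG‡/RT)`, 1 M standard state), reversible
  ODE models obeying detailed balance, stiff integration, and
  autocatalysis metrics (per-capita growth of the C₂ pool, parasitic
  leakage fraction, food half-depletion time).
- **synth** — seeded generators for thermodynamically consistent synthetic
  species/reaction sets, controlled inconsistency injection, and
  residual-based localization of the corrupted entry.
- **packaged map** — a transcription of the published bisulfite/formose
  free-energy map (species, transition states, reactions, isomer groups)
  with per-value provenance markers and explicit flags for the printed
  arithmetic discrepancies (see `src/fesnet/data/notes.json`).

## CLI

```sh
fesnet validate                     # element balance + Hess audit (exit 1 on failure)
fesnet delta shift_6_8              # ΔG / ΔG‡ of one reaction of the packaged map
fesnet speciate pentopyranose_24    # Boltzmann fractions + ranking for a group
fesnet simulate --variant bisulfite # integrate the packaged autocatalysis scenario
fesnet simulate --variant no_retro  # ... without the C2-regenerating step
fesnet fixture --out dump/          # dump tables, JSON and GraphML
fesnet generate --seed 3 --out gen/ # synthetic species/reaction tables
fesnet grel --species s.tsv --components c.tsv   # G_rel from raw components
```

`validate` accepts `--species/--reactions` TSV paths to audit user maps;
reaction tables may carry an `overrides` column with reaction-local
`G_rel` replacements (this is what the corruption tooling emits).

## Notes on conventions

- Energies are kcal/mol throughout; R = 1.9872041×10⁻³ kcal/(mol·K);
  default temperature 298.15 K.
- Water (and the other reference species) may appear freely in reactions
  and contribute `G_rel = 0`; water's standard state follows the map's
  implicit 1 M-equivalent convention. In kinetic models, buffered species
  (default: water) are held at unit activity and folded into the rate
  constants.
- Enantiomer pairs are represented once with `degeneracy = 2`.
- Steps without an optimized transition state receive an imputed barrier
  (default 2.0 kcal/mol, per-reaction overrides available), and a global
  barrier offset supports sensitivity runs against the known systematic
  barrier error of the upstream protocol.
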