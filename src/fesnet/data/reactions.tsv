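# Transcribed free-energy map: reaction list.
# reactants/products: "+"-separated species ids; an integer followed by a
# space is a stoichiometric coefficient. Reference species appear freely
# and contribute G_rel = 0.
id	reactants	products	ts_id	category	annotation
add_c1_o	1 + H2SO3	2	ts_add_c1_o	adduct_formation	O-attack on the C1 carbonyl; dG -3.0, barrier +5.2
add_c1_s	1 + H2SO3	3	ts_add_c1_s	adduct_formation	S-attack on the C1 carbonyl; dG +2.6, barrier +11.8
add_c2_carbonyl_i	4 + H2SO3	6	ts_add_c2_i	adduct_formation	hydroxyl O-attack; barrier +12.6; forming O..C 2.10 A
add_c2_carbonyl_ii	4 + H2SO3	6	ts_add_c2_ii	adduct_formation	sulfoxide O-attack; barrier +11.4; forming O..C 1.98 A
add_c2_hydroxyl	4 + H2SO3	7 + H2O	ts_add_c2_so2	adduct_formation	hydroxyl-on-S with SO2 moiety; barrier +2.6; forming O..S 1.94 A; printed dG -1.3 vs tabulated -1.4 (see notes)
shift_6_9	6	9	ts_shift_6_9	rearrangement	ring-shift entry; flanking TS below the intermediate (submerged)
shift_9_8	9	8	ts_shift_9_8	rearrangement	ring-shift exit; flanking TS below the intermediate (submerged)
shift_6_8	6	8	ts_shift_sym	rearrangement	direct shift through the symmetric TS
dehydr_8_7	8	7 + H2O	-	dehydration	0.8 downhill; hydration barrier ~13
cann_c1	1 + 10	11 + 12	ts_cann_c1	cannizzaro	C1 disproportionation; dG -22.2, barrier +28.0
hydrate_c1	1 + H2O	10	-	other	C1 hydration
cann_c1_bis	1 + 2	11 + 13	-	cannizzaro	dG -8.9; barrier ~5 above cann_c1
xcann_i	4 + 1 + H2O	14 + 12	ts_xcann_i	cannizzaro	cross reaction, no sulfur; dG -16.3, barrier +32.7
xcann_ii	7 + 1 + H2O	15 + 12	-	cannizzaro	adduct on the C2 partner, spectator; dG close to xcann_i
xcann_iii	4 + 2	14 + 13	-	cannizzaro	adduct on the oxidized C1 partner; dG -3.1
xcann_iv	7 + 2	15 + 13	-	cannizzaro	adducts on both partners; dG -5.2
aldol_c2_keep	7 + 1	17	ts_aldol_keep	aldol	adduct retained; TS +19.3 (enolization lumped in)
aldol_c2_elim	7 + 1 + H2O	16 + H2SO3	ts_aldol_elim	aldol	intramolecular catalysis with SO2 elimination; TS +5.3; breaking O..S 2.15 A
add_c3	16 + H2SO3	17 + H2O	-	adduct_formation	dG +0.7; barrier ~2 (imputed)
shift_17_18	17	18	-	rearrangement	terminal vs central adduct; via SO2 removal/re-addition
aldol_c3_elim	17 + 1 + H2O	20 + H2SO3	-	aldol	intramolecularly catalyzed; dG -12.6
aldol_c3_branch21	17 + 1	21	-	aldol	branched dead-end product; printed dG -7.3 vs tabulated -7.0 (see notes)
aldol_c3_branch22	18 + 1	22	-	aldol	branched dead-end product; adduct remote from the forming bond
aldol_c3_keep1	18 + 1	23	-	aldol	adduct retained at carbon 1; dG -12.7
aldol_c3_keep3	17 + 1	24	-	aldol	adduct retained at carbon 3; dG -11.9
taut_24_ery	24	26ery	ts_taut_ery	tautomerization	ketose-to-aldose; enol step barrier +21.5, aldose-forming TS +2.6
taut_24_thr	24	26thr	ts_taut_thr	tautomerization	ketose-to-aldose; enol step barrier +21.5, aldose-forming TS +4.4
retro_thr	26thr + H2O	4 + 4 + H2SO3	-	retro_aldol	overall regeneration after enol tautomerization; dG -5.7
retro_ery	26ery + H2O	4 + 4 + H2SO3	-	retro_aldol	overall regeneration after enol tautomerization; dG -6.6
retro_thr_enol	26thr + H2O	4 + 4ec + H2SO3	-	retro_aldol	fragmentation step before enol relaxation; dG +2.5
retro_ery_enol	26ery + H2O	4 + 4et + H2SO3	-	retro_aldol	fragmentation step before enol relaxation; dG +3.3
retro_thr_k	26thr + H2O	4 + 6	ts_retro_thr	retro_aldol	kinetic decomposition of retro_thr (second product released via 6); barrier +18.6; breaking C..C 1.84 A, S..O 2.14 A
retro_ery_k	26ery + H2O	4 + 6	ts_retro_ery	retro_aldol	kinetic decomposition of retro_ery; barrier +20.3; breaking C..C 1.94 A, S..O 2.03 A
retro_ns_thr	29thr	4 + 4	ts_retro_ns	retro_aldol	non-sulfur analog; dG +2.9, barrier ~32 (approx TS)
strip_24_ns	24 + H2O	29thr + H2SO3	-	tautomerization	adduct removal + ketose-to-aldose lumped for the non-sulfur variant
retro_ns_ery	29ery	4 + 4	-	retro_aldol	non-sulfur analog; dG +2.2
taut_4ec	4ec	4	-	tautomerization	enol relaxation
taut_4et	4et	4	-	tautomerization	enol relaxation
aldol_c2c3_lyx24	7 + 17	30lyx	-	aldol	open-chain 2,4 adduct; slightly downhill for lyxose
aldol_c2c3_rib24	7 + 17	31rib	-	aldol	overall with pyranose ring closure
aldol_c2c3_ara24	7 + 17	31ara	-	aldol	overall with pyranose ring closure
aldol_c2c3_xyl25	7 + 18	32xyl	-	aldol	open-chain 2,5 adduct; slightly exergonic for xylose
aldol_c2c3_rib25	7 + 18	33rib	-	aldol	overall with furanose ring closure
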