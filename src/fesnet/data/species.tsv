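# Transcribed free-energy map: species registry.
# g_rel in kcal/mol on the CO2/H2/H2O/H2SO3 = 0 reference scale.
# provenance: text = value printed directly in the running text;
#             text-derived = one arithmetic step from printed values;
#             assigned = consistent split of an under-determined printed sum
#                        (one free parameter; all printed reaction energies
#                        are reproduced regardless of the split);
#             approx = printed only as an approximate value ("~").
id	formula	role	g_rel	degeneracy	tags	provenance
CO2	CO2	minimum	0.0	1	reference	text
H2	H2	minimum	0.0	1	reference	text
H2O	H2O	minimum	0.0	1	reference	text
H2SO3	H2SO3	minimum	0.0	1	reference	text
1	CH2O	minimum	2.6	1	c1;aldehyde	text
2	CH4O4S	minimum	-0.4	1	c1;adduct;o_attack	text-derived
3	CH4O4S	minimum	5.2	1	c1;adduct;s_attack	text-derived
4	C2H4O2	minimum	-11.4	1	c2;aldehyde	text
4ec	C2H4O2	minimum	-3.2	1	c2;enol;cis	text-derived
4et	C2H4O2	minimum	-1.5	1	c2;enol;trans	text-derived
6	C2H6O5S	minimum	-9.4	1	c2;adduct;carbonyl	text
7	C2H4O4S	minimum	-12.8	1	c2;adduct;hydroxyl	text
8	C2H6O5S	minimum	-12.0	1	c2;adduct;hydrate	text
9	C2H6O5S	minimum	18.3	1	c2;ring_intermediate	text
10	CH4O2	minimum	2.7	1	c1;hydrate	text-derived
11	CH4O	minimum	3.3	1	c1;alcohol	assigned
12	CH2O2	minimum	-20.2	1	c1;acid	assigned
13	CH2O4S	minimum	-10.0	1	c1;acid;adduct	assigned
14	C2H6O2	minimum	-4.9	1	c2;diol	assigned
15	C2H6O4S	minimum	-8.4	1	c2;diol;adduct	assigned
16	C3H6O3	minimum	-18.1	1	c3;aldose	text-derived
17	C3H6O5S	minimum	-17.4	1	c3;adduct;position2	text
18	C3H6O5S	minimum	-17.2	1	c3;adduct;position1	text
20	C4H8O4	minimum	-27.4	1	c4;ketose	text
21	C4H8O6S	minimum	-21.8	1	c4;branched;adduct;dead_end	text
22	C4H8O6S	minimum	-22.6	1	c4;branched;adduct;dead_end	text-derived
23	C4H8O6S	minimum	-27.3	1	c4;ketose;adduct;position1	text-derived
24	C4H8O6S	minimum	-26.7	1	c4;ketose;adduct;position3	text-derived
26thr	C4H8O6S	minimum	-17.1	2	c4;aldose;adduct;threose	text-derived
26ery	C4H8O6S	minimum	-16.2	2	c4;aldose;adduct;erythrose	text-derived
29thr	C4H8O4	minimum	-25.7	2	c4;aldose;threose;non_sulfur	text-derived
29ery	C4H8O4	minimum	-25.0	2	c4;aldose;erythrose;non_sulfur	text-derived
30lyx	C5H10O9S2	minimum	-31.6	2	c5;open_chain;lyxose;adduct24	text
31rib	C5H10O9S2	minimum	-33.9	2	c5;pyranose;ribose;adduct24	text
31ara	C5H10O9S2	minimum	-31.1	2	c5;pyranose;arabinose;adduct24	text-derived
32xyl	C5H10O9S2	minimum	-32.8	2	c5;open_chain;xylose;adduct25	text
33rib	C5H10O9S2	minimum	-33.2	2	c5;furanose;ribose;adduct25	text
ts_add_c1_o	CH4O4S	transition_state	7.8	1	ts	text-derived
ts_add_c1_s	CH4O4S	transition_state	14.4	1	ts	text-derived
ts_add_c2_i	C2H6O5S	transition_state	1.2	1	ts;eight_center	text-derived
ts_add_c2_ii	C2H6O5S	transition_state	0.0	1	ts;eight_center	text-derived
ts_add_c2_so2	C2H6O5S	transition_state	-8.8	1	ts;six_center	text-derived
ts_shift_6_9	C2H6O5S	transition_state	16.9	1	ts;ring_shift	text
ts_shift_9_8	C2H6O5S	transition_state	17.7	1	ts;ring_shift	text
ts_shift_sym	C2H6O5S	transition_state	24.6	1	ts;ring_shift;symmetric	text
ts_cann_c1	C2H6O3	transition_state	33.3	1	ts;cannizzaro	text-derived
ts_xcann_i	C3H8O4	transition_state	23.9	1	ts;cannizzaro	text-derived
ts_aldol_keep	C3H6O5S	transition_state	19.3	1	ts;aldol	text
ts_aldol_elim	C3H8O6S	transition_state	5.3	1	ts;aldol;so2_elimination	text
ts_taut_ery	C4H8O6S	transition_state	2.6	1	ts;tautomerization	text
ts_taut_thr	C4H8O6S	transition_state	4.4	1	ts;tautomerization	text
ts_retro_thr	C4H10O7S	transition_state	1.5	1	ts;retro_aldol	text-derived
ts_retro_ery	C4H10O7S	transition_state	4.1	1	ts;retro_aldol	text-derived
ts_retro_ns	C4H8O4	transition_state	6.3	1	ts;retro_aldol;non_sulfur	approx
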