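genome_id	n_proteins	n_orfans	n_cog_annotated	fam1	fam2	fam3	fam_gt3
M_agalactiae_PG2	742	267	475	335	42	10	4
M_agalactiae_uid46679	813	291	522	332	42	15	10
M_arthritidis_158L3_1	631	214	417	347	20	3	3
M_bovis_Hubei_1	801	279	522	346	37	11	11
M_bovis_PG45	765	239	526	354	43	9	7
M_capricolum_ATCC_27343	812	236	576	390	58	10	7
M_conjunctivae	692	272	420	323	39	0	4
M_crocodyli_MP145	689	199	490	380	37	6	4
M_fermentans_JER	797	247	550	388	38	8	12
M_fermentans_M64	1049	459	590	383	35	11	18
M_gallisepticum_R_low	763	274	489	357	43	4	6
M_genitalium_G37	475	91	384	330	15	4	3
M_haemofelis_Langford_1	1545	1258	287	230	16	2	1
M_hominis_ATCC_23114	523	145	378	315	21	1	4
M_hyopneumoniae_232	691	254	437	331	39	1	3
M_hyopneumoniae_7448	657	214	443	333	38	1	4
M_hyopneumoniae_J	657	186	471	344	44	2	4
M_hyorhinis_HUB_1	658	194	464	339	36	7	2
M_leachii_PG50	882	316	566	398	50	9	8
M_mobile_163K	633	183	450	370	26	6	2
M_mycoides_capri_LC_95010	922	303	619	400	55	6	14
M_mycoides_SC_PG1	1017	325	692	397	55	15	16
M_penetrans_HF_2	1037	379	658	447	54	10	14
M_pneumoniae_M129	648	203	445	359	19	6	6
M_pulmonis_UAB_CTIP	782	222	560	387	36	8	17
M_putrefaciens_KS1	650	176	474	379	34	4	3
M_suis_Illinois	845	592	253	209	14	0	2
M_suis_KI3806	794	553	241	212	11	1	1
M_synoviae_53	659	180	479	357	33	10	5
U_parvum_serovar_3_ATCC_27815	609	196	413	346	25	1	2
U_parvum_serovar_3_ATCC_700970	614	173	441	360	29	3	2
U_urealyticum_serovar_10_ATCC_33699	646	230	416	342	25	3	2
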