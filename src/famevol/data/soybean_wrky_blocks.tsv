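gene_a	gene_b	n_anchors	mean_ks	sd_ks	reported_age_myr
Glyma01g05050	Glyma18g16170	4	0.60	0.20	49
Glyma01g06550	Glyma02g12490	3	0.17	0.06	14
Glyma01g06870	Glyma02g12830	4	0.16	0.08	13
Glyma01g31920	Glyma03g05220	5	0.19	0.06	16
Glyma01g31920	Glyma18g44030	3	0.71	0.22	58
Glyma01g39600	Glyma11g05650	17	0.17	0.07	14
Glyma01g43420	Glyma05g36970	5	0.70	0.19	57
Glyma01g43420	Glyma08g02580	4	0.68	0.17	56
Glyma02g01420	Glyma03g37940	8	0.67	0.11	55
Glyma02g01420	Glyma10g01450	19	0.20	0.11	16
Glyma02g01420	Glyma19g40560	7	0.72	0.17	59
Glyma02g15920	Glyma03g31630	6	0.60	0.16	49
Glyma02g15920	Glyma10g03820	11	0.15	0.11	12
Glyma02g36510	Glyma17g08170	18	0.13	0.05	11
Glyma02g45530	Glyma14g03280	6	0.12	0.05	10
Glyma02g46690	Glyma08g43770	8	0.61	0.19	50
Glyma02g46690	Glyma14g01980	16	0.13	0.07	11
Glyma02g47650	Glyma14g01010	21	0.14	0.08	11
Glyma03g00460	Glyma09g41050	5	0.51	0.12	42
Glyma03g31630	Glyma10g03820	6	0.55	0.10	45
Glyma03g33380	Glyma19g36100	21	0.19	0.17	16
Glyma03g37870	Glyma19g40470	18	0.15	0.07	12
Glyma03g37940	Glyma10g01450	9	0.73	0.16	60
Glyma03g37940	Glyma19g40560	17	0.15	0.07	12
Glyma03g38360	Glyma19g40950	11	0.16	0.09	13
Glyma03g41750	Glyma07g06320	5	0.66	0.23	54
Glyma03g41750	Glyma16g02960	3	0.62	0.26	51
Glyma03g41750	Glyma19g44380	19	0.18	0.13	15
Glyma04g08060	Glyma06g08120	14	0.18	0.12	15
Glyma04g39620	Glyma06g15260	14	0.23	0.19	19
Glyma04g39650	Glyma05g31800	4	0.72	0.19	59
Glyma04g39650	Glyma06g15220	15	0.22	0.19	18
Glyma04g39650	Glyma08g15050	4	0.66	0.19	54
Glyma04g40130	Glyma06g14720	18	0.25	0.25	20
Glyma05g01280	Glyma06g20300	6	0.57	0.21	47
Glyma05g25330	Glyma08g08340	12	0.21	0.19	17
Glyma05g25770	Glyma08g08720	14	0.20	0.15	16
Glyma05g29310	Glyma08g12460	18	0.16	0.07	13
Glyma05g31800	Glyma06g15220	4	0.63	0.22	52
Glyma05g31800	Glyma08g15050	19	0.14	0.08	11
Glyma05g36970	Glyma08g02580	17	0.22	0.15	18
Glyma05g37390	Glyma08g02160	17	0.14	0.08	11
Glyma06g15220	Glyma08g15050	5	0.68	0.23	56
Glyma06g15260	Glyma08g15210	3	0.71	0.21	58
Glyma06g46420	Glyma12g10350	9	0.23	0.19	19
Glyma06g46420	Glyma13g38630	6	0.72	0.11	59
Glyma07g02630	Glyma08g23380	15	0.22	0.18	18
Glyma07g02630	Glyma13g44730	6	0.56	0.18	46
Glyma07g02630	Glyma15g00570	6	0.54	0.15	44
Glyma07g06320	Glyma16g02960	12	0.16	0.07	13
Glyma07g06320	Glyma19g44380	5	0.61	0.17	50
Glyma07g36640	Glyma15g14860	5	0.59	0.21	48
Glyma07g36640	Glyma17g03950	13	0.23	0.23	19
Glyma07g36640	Glyma09g03900	5	0.73	0.18	60
Glyma07g39250	Glyma09g00820	5	0.63	0.15	52
Glyma07g39250	Glyma15g11680	7	0.65	0.18	53
Glyma07g39250	Glyma17g01490	23	0.17	0.11	14
Glyma08g23380	Glyma13g44730	4	0.49	0.18	40
Glyma08g23380	Glyma15g00570	4	0.52	0.17	43
Glyma08g26230	Glyma18g49830	8	0.21	0.08	17
Glyma08g43770	Glyma14g01980	7	0.56	0.13	46
Glyma09g00820	Glyma15g11680	15	0.20	0.14	16
Glyma09g00820	Glyma17g01490	5	0.67	0.21	55
Glyma09g03450	Glyma15g14370	14	0.20	0.15	16
Glyma09g03900	Glyma15g14860	12	0.25	0.21	20
Glyma09g03900	Glyma17g03950	3	0.59	0.17	48
Glyma09g06980	Glyma13g00380	5	0.69	0.18	57
Glyma09g06980	Glyma15g18250	7	0.22	0.21	18
Glyma09g06980	Glyma17g06450	5	0.56	0.11	46
Glyma09g39000	Glyma18g47350	11	0.19	0.10	16
Glyma09g39040	Glyma18g47300	13	0.18	0.10	15
Glyma09g41050	Glyma18g44560	12	0.16	0.06	13
Glyma10g01450	Glyma19g40560	6	0.70	0.17	57
Glyma10g37460	Glyma20g30290	11	0.13	0.05	11
Glyma11g05650	Glyma17g18480	3	0.71	0.23	58
Glyma12g10350	Glyma13g38630	4	0.73	0.10	60
Glyma12g33990	Glyma13g36540	12	0.23	0.20	19
Glyma13g00380	Glyma17g06450	17	0.19	0.13	16
Glyma13g17800	Glyma17g04710	17	0.20	0.17	16
Glyma13g44730	Glyma15g00570	13	0.12	0.06	10
Glyma14g11440	Glyma17g34210	6	0.32	0.19	26
Glyma14g11920	Glyma17g33920	5	0.17	0.05	14
Glyma15g11680	Glyma17g01490	7	0.67	0.20	55
Glyma15g14860	Glyma17g03950	5	0.58	0.24	48
Glyma15g18250	Glyma17g06450	4	0.68	0.16	56
Glyma16g02960	Glyma19g44380	3	0.58	0.17	48
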