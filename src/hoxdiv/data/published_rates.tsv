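gene	group	super_label	n_taxa	n_sites	mean_p_percent	age_my	printed_rate
lab	Gastropoda	non-insect	5	75	32	528	0.061
lab	Cephalopoda	non-insect	3	75	12	520	0.023
lab	Bivalvia	non-insect	5	75	30.7	510	0.060
lab	Crustacea	non-insect	5	75	23.6	510	0.046
lab	Insecta	insect	9	75	26	396	0.066
lab	Mammalia Hox-A	non-insect	6	75	15.3	195	0.078
lab	Mammalia Hox-B	non-insect	6	75	6.1	195	0.031
lab	Mammalia Hox-D	non-insect	5	75	9.5	195	0.049
pb	Gastropoda	non-insect	4	75	38.8	528	0.073
pb	Bivalvia	non-insect	3	75	29.3	510	0.057
pb	Crustacea	non-insect	6	75	27.1	510	0.053
pb	Insecta	insect	7	75	27.4	396	0.069
pb	Mammalia Hox-A	non-insect	6	75	4.3	195	0.022
pb	Mammalia Hox-B	non-insect	6	75	7	195	0.036
Dfd	Gastropoda	non-insect	4	72	34.7	528	0.066
Dfd	Bivalvia	non-insect	3	72	26.1	510	0.051
Dfd	Crustacea	non-insect	7	72	26.9	510	0.053
Dfd	Insecta	insect	14	72	28	396	0.071
Dfd	Mammalia Hox-A	non-insect	5	72	4.4	195	0.023
Dfd	Mammalia Hox-B	non-insect	6	72	4.6	195	0.024
Dfd	Mammalia Hox-C	non-insect	5	72	1	195	0.005
Dfd	Mammalia Hox-D	non-insect	5	72	3.7	195	0.019
Scr	Gastropoda	non-insect	3	76	23.1	528	0.044
Scr	Cephalopoda	non-insect	4	76	25.1	520	0.048
Scr	Bivalvia	non-insect	3	76	21.8	510	0.043
Scr	Crustacea	non-insect	6	76	28.2	510	0.055
Scr	Insecta	insect	15	76	24.5	396	0.062
Scr	Mammalia Hox-A	non-insect	6	76	6.7	195	0.034
Scr	Mammalia Hox-B	non-insect	5	76	1	195	0.005
Scr	Mammalia Hox-C	non-insect	6	76	5.1	195	0.026
Antp	Gastropoda	non-insect	3	76	25	528	0.047
Antp	Cephalopoda	non-insect	3	76	20	520	0.038
Antp	Bivalvia	non-insect	4	76	19.4	510	0.038
Antp	Crustacea	non-insect	6	76	20	510	0.039
Antp	Insecta	insect	16	76	19.7	396	0.050
Antp	Mammalia Hox-A	non-insect	4	76	8.3	195	0.043
Antp	Mammalia Hox-B	non-insect	4	76	5.9	195	0.030
Antp	Mammalia Hox-C	non-insect	4	76	11.1	195	0.057
Ubx	Gastropoda	non-insect	3	76	26.9	528	0.051
Ubx	Cephalopoda	non-insect	2	76	1.2	520	0.002
Ubx	Bivalvia	non-insect	2	76	14	510	0.027
Ubx	Crustacea	non-insect	8	76	26.1	510	0.051
Ubx	Insecta	insect	14	76	23.4	396	0.059
Ubx	Mammalia Hox-A	non-insect	5	76	5.3	195	0.027
Ubx	Mammalia Hox-B	non-insect	5	76	4.4	195	0.023
abdA	Gastropoda	non-insect	3	75	25.6	528	0.048
abdA	Cephalopoda	non-insect	3	75	25.8	520	0.050
abdA	Bivalvia	non-insect	3	75	33.6	510	0.066
abdA	Crustacea	non-insect	5	75	23.2	510	0.045
abdA	Insecta	insect	14	75	23.8	396	0.060
abdA	Mammalia Hox-B	non-insect	5	75	4.5	195	0.023
abdA	Mammalia Hox-C	non-insect	4	75	6.8	195	0.035
abdA	Mammalia Hox-D	non-insect	4	75	8	195	0.041
abdB	Gastropoda	non-insect	2	75	28.6	528	0.054
abdB	Cephalopoda	non-insect	2	75	15.9	520	0.031
abdB	Crustacea	non-insect	5	75	23.6	510	0.046
abdB	Insecta	insect	10	75	18.8	396	0.047
abdB	Mammalia Hox-A	non-insect	4	75	7.5	195	0.038
abdB	Mammalia Hox-C	non-insect	5	75	2.4	195	0.012
abdB	Mammalia Hox-D	non-insect	5	75	3.3	195	0.017
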