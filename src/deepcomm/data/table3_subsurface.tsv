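Site	Latitude (S)	Longitude (E)	Elevation (masl)	Depth (mbs)	Temperature (C)	pH	TDS (ppm)	O2 (M)	CH4 (M)	H2 (M)	Na+ (M)	K+ (M)	Ca2+ (M)	Mg2+ (M)	NO3- (M)	Cl- (M)	SO42- (M)	HPO42- (M)	DOC (M)	DIC (M)
Be326_2011	28°14′24.3″	26°47′49.2″	1375	1339	36.9	8.83	4473	<3.1e-7	2.0e-3	1.3e-7	7.8e-2	7.3e-4	2.9e-3	5.6e-5	3.7e-7	7.0e-2	1.4e-4	<1.1e-6	1.5e-5	5.1e-4
Be326_2012	28°14′24.3″	26°47′49.2″	1375	1339	38.1	8.55	3586	9.4e-6	9.0e-4	8.9e-9	4.8e-2	8.5e-4	3.9e-3	2.6e-5	6.0e-6	6.2e-2	6.2e-4	3.0e-7	2.9e-5	3.3e-4
Dr5IPC	26°25′12″	27°30′10″	1654	1046	26.8	7.39	188	1.9e-6	2.6e-5	3.2e-9	2.2e-3	5.6e-5	5.0e-4	4.0e-4	1.5e-6	1.4e-3	1.4e-4	1.6e-7	8.5e-5	2.4e-3
FI88	28°22′43″	23°26′45″	1545	1056	28.6	7.9	1282	1.3e-6	<1e-4	<1e-8	9.9e-3	1.8e-4	5.6e-3	1.5e-4	1.5e-5	2.2e-2	3.0e-4	3.5e-7	1.3e-4	5.4e-5
MM51940	27°58′24″	26°52′39″	1386	1900	40.7	7.71-8.18	3120	1.9e-6	8.9e-3	1.9e-7	4.5e-2	4.0e-4	1.9e-3	9.9e-5	9.7e-7	5.5e-2	7.0e-6	<3.2e-7	4.5e-5	4.3e-4
NO14	24°49′43″	27°20′26″	985	2100	>65	8.48	2374	3.1e-6	3.2e-4	4.5e-6	9.4e-2	4.1e-3	2.5e-3	6.4e-4	n.a.	5e-2	n.a.	1.1e-7	2.6e-5	5.2e-4
TT109	26°24′55″	27°27′45″	1681	3136	48.7	8.19	296	6.3e-6	2.3e-3	3.6e-7	3.4e-3	4.2e-5	5.2e-4	3.4e-5	1.1e-7	3.2e-3	1.0e-4	1.2e-6	3.9e-5	6.9e-4
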