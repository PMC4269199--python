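Site	Latitude (S)	Longitude (E)	Elevation (masl)	Temperature (C)	Estimated depth (m)	pH	TDS (ppm)	O2 (M)	Na+ (M)	K+ (M)	Ca2+ (M)	Mg2+ (M)	NO3- (M)	Cl- (M)	SO42- (M)	HPO42- (M)	DIC (M)
Eiland	23°39′31″	30°40′23.6″	433	40-42	700-1050	7.63	>1862	n.a.	2.7e-2	5.6e-4	1.3e-3	3.9e-4	4.0e-5	2.8e-2	1.5e-3	2.6e-4	<d.l.
Mphephu	22°54′20″	30°10′38″	796	43	767-1150	8.08-8.19	275	1.3e-4	1.9e-3	2.9e-5	3.4e-4	4.6e-4	3.4e-5	1.1e-3	9.5e-5	<d.l.	2.5e-3
Sagole	22°31′45.4″	30°40′50″	446	45	830-1250	9.24-9.70	237	1.9e-5	2.8e-3	2.8e-5	3.3e-5	2.9e-6	<d.l.	1.4e-3	1.9e-4	<d.l.	2.0e-3
Siloam	22°53′22.6″	30°11′39″	841	63-67	1500-2250	8.8-9.5	252	6.9e-5	2.9e-3	7.2e-5	3.4e-5	5.5e-4	<d.l.	1.3e-3	1.1e-5	<d.l.	2.0e-3
Souting	23°25′9″	30°54′44″	389	40.1-43.9	730-1100	7.8	10130	n.a.	1.5e-1	7.9e-4	6.0e-3	3.3e-3	4.3e-5	1.6e-1	7.9e-3	<2.5e-5	n.a.
Tshipise	22°36′31.5″	30°10′16.7″	542	58	1267-1900	8.3-8.94	523	6.1e-5	6.8e-3	1.1e-4	1.4e-4	6.7e-6	9.8e-6	4.8e-3	5.5e-4	2.8e-5	2.2e-3
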