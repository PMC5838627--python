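# Single internal mismatch nearest-neighbor parameters
# (Allawi & SantaLucia 1997, 1998a-c; Peyret et al. 1999).
# stack XY/ZW = 5'-XY-3' paired with 3'-ZW-5'; one of the two pairs is a mismatch.
stack	dH_kcal_mol	dS_cal_molK
AA/TA	1.2	1.7
AA/TC	2.3	4.6
AA/TG	-0.6	-2.3
AC/TA	5.3	14.6
AC/TC	0.0	-4.4
AC/TT	0.7	0.2
AG/TA	-0.7	-2.3
AG/TG	-3.1	-9.5
AG/TT	1.0	0.9
AT/TC	-1.2	-6.2
AT/TG	-2.5	-8.3
AT/TT	-2.7	-10.8
CA/GA	-0.9	-4.2
CA/GC	1.9	3.7
CA/GG	-0.7	-2.3
CC/GA	0.6	-0.6
CC/GC	-1.5	-7.2
CC/GT	-0.8	-4.5
CG/GA	-4.0	-13.2
CG/GG	-4.9	-15.3
CG/GT	-4.1	-11.7
CT/GC	-1.5	-6.1
CT/GG	-2.8	-8.0
CT/GT	-5.0	-15.8
GA/CA	-2.9	-9.8
GA/CC	5.2	14.2
GA/CG	-0.6	-1.0
GC/CA	-0.7	-3.8
GC/CC	3.6	8.9
GC/CT	2.3	5.4
GG/CA	0.5	3.2
GG/CG	-6.0	-15.8
GG/CT	3.3	10.4
GG/TT	5.8	16.3
GT/CC	5.2	13.5
GT/CG	-4.4	-12.3
GT/CT	-2.2	-8.4
GT/TG	4.1	9.5
TA/AA	4.7	12.9
TA/AC	3.4	8.0
TA/AG	0.7	0.7
TC/AA	7.6	20.2
TC/AC	6.1	16.4
TC/AT	1.2	0.7
TG/AA	3.0	7.4
TG/AG	1.6	3.6
TG/AT	-0.1	-1.7
TG/GT	-1.4	-6.2
TT/AC	1.0	0.7
TT/AG	-1.3	-5.3
TT/AT	0.2	-1.5
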