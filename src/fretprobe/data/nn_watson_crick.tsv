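# Unified Watson-Crick nearest-neighbor parameters (SantaLucia 1998).
# stack XY/ZW = 5'-XY-3' paired with 3'-ZW-5'. init_AT / init_GC are per-terminus
# duplex initiation terms keyed by the terminal base pair.
stack	dH_kcal_mol	dS_cal_molK
AA/TT	-7.9	-22.2
AT/TA	-7.2	-20.4
CA/GT	-8.5	-22.7
CG/GC	-10.6	-27.2
CT/GA	-7.8	-21.0
GA/CT	-8.2	-22.2
GC/CG	-9.8	-24.4
GG/CC	-8.0	-19.9
GT/CA	-8.4	-22.4
TA/AT	-7.2	-21.3
init_AT	2.3	4.1
init_GC	0.1	-2.8
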