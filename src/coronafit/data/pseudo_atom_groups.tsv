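# Pseudo-atom / atomic-group lookup table.
# label	element	n_h	n_e	v_vdw
# n_e: electrons of the group (heavy atom + bonded hydrogens).
# v_vdw: group excluded volume in A^3, (4/3) pi r^3 from effective group radii.
C	C	0	6	16.5
CH	C	1	7	21.7
CH2	C	2	8	26.5
CH3	C	3	9	32.0
N	N	0	7	2.5
NH	N	1	8	7.6
NH2	N	2	9	12.8
NH3	N	3	10	18.2
O	O	0	8	9.2
OH	O	1	9	14.1
S	S	0	16	19.9
SH	S	1	17	24.8
TOY	X	0	7	20.0
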