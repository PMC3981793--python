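# Reduced nearest-neighbor parameter set for the built-in folding engine.
# Stacks carry enthalpy and entropy (dG(T) = dH - T*dS); loops are tabulated
# as dG at 37 C and rescaled as purely entropic terms.
# version: builtin-reduced-v1
[STACK]
# context (5'pair/3'pair)	dH kcal/mol	dS kcal/(mol*K)
AU/AU	-10.75	-0.0293262
AU/UA	-9.66	-0.0260936
AU/CG	-16.30	-0.0451959
AU/GC	-16.83	-0.0466034
AU/GU	-6.85	-0.0188948
AU/UG	-7.36	-0.0202018
UA/AU	-10.95	-0.0305012
UA/UA	-10.75	-0.0293262
UA/CG	-15.86	-0.0435056
UA/GC	-18.34	-0.0511255
UA/GU	-6.97	-0.0190582
UA/UG	-7.25	-0.0196249
CG/AU	-18.34	-0.0511255
CG/UA	-16.83	-0.0466034
CG/CG	-19.95	-0.0541691
CG/GC	-22.42	-0.0615934
CG/GU	-12.68	-0.0344685
CG/UG	-13.50	-0.0372729
GC/AU	-15.86	-0.0435056
GC/UA	-16.30	-0.0451959
GC/CG	-23.61	-0.0658373
GC/GC	-19.95	-0.0541691
GC/GU	-12.68	-0.0349836
GC/UG	-11.09	-0.0300786
GU/AU	-7.25	-0.0196249
GU/UA	-7.36	-0.0202018
GU/CG	-11.09	-0.0300786
GU/GC	-13.50	-0.0372729
GU/GU	-3.32	-0.0090138
GU/UG	-3.21	-0.0087692
UG/AU	-6.97	-0.0190582
UG/UA	-6.85	-0.0188948
UG/CG	-12.68	-0.0349836
UG/GC	-12.68	-0.0344685
UG/GU	-3.40	-0.0093700
UG/UG	-3.32	-0.0090138
[HAIRPIN]
# loop size	dG37 kcal/mol
3	5.40
4	5.71
5	5.95
6	6.15
7	6.31
8	6.46
9	6.58
10	6.70
11	6.80
12	6.90
13	6.98
14	7.06
15	7.14
16	7.21
17	7.27
18	7.33
19	7.39
20	7.45
21	7.50
22	7.55
23	7.60
24	7.64
25	7.69
26	7.73
27	7.77
28	7.81
29	7.85
30	7.88
[LOOP]
# total unpaired	dG37 kcal/mol
1	3.80
2	4.55
3	4.98
4	5.30
5	5.54
6	5.73
7	5.90
8	6.04
9	6.17
10	6.28
11	6.39
12	6.48
13	6.57
14	6.65
15	6.72
16	6.79
17	6.86
18	6.92
19	6.98
20	7.03
21	7.08
22	7.13
23	7.18
24	7.23
25	7.27
26	7.31
27	7.35
28	7.39
29	7.43
30	7.47
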