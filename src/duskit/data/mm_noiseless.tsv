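# Synthetic noiseless Michaelis-Menten dataset: v = kcat*E*S/(Km+S)
# generating parameters: kcat = 0.48 /s, Km = 17 uM, enzyme concentration 1 uM
S_uM	v_uM_per_s
2	0.0505263157895
5	0.109090909091
10	0.177777777778
17	0.24
30	0.306382978723
60	0.374025974026
120	0.420437956204
240	0.448249027237
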