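cell_type	direction	n_ouabain	max_fold_ouabain	n_kfree	max_fold_kfree	n_both
hela	up	338	13.78	1371	46.86	278
hela	down	481	2.85	1707	7.96	406
huvec	up	400	9.68	1471	64.81	355
huvec	down	486	2.40	1447	5.33	379
rvsmc	up	1288	9.46	1872	24.32	894
rvsmc	down	1903	4.15	1805	7.50	945
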