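pirna_id	log2fc	pvalue	padj
piR-hsa-28,318	-5.340465873	3.27E-09	6.24E-07
piR-hsa-12,206	-5.215886646	5.42E-07	5.18E-05
piR-hsa-26,039	-4.532419859	5.18E-05	0.001041
piR-hsa-1823	-4.19153802	0.004378	0.02424
piR-hsa-26,872	-3.458270472	0.00238	0.015589
piR-hsa-1849	-3.419378179	0.006588	0.031491
piR-hsa-28,849	-3.404696639	0.000889	0.008487
piR-hsa-1361	-3.150200426	0.012918	0.04988
piR-hsa-3178	-3.144981842	0.009941	0.041277
piR-hsa-28,848	-3.124585935	0.009553	0.040546
piR-hsa-28,319	-3.016459647	0.001276	0.010719
piR-hsa-28,019	-2.649275192	0.000255	0.003747
piR-hsa-17,444	-2.610043613	0.000345	0.00471
piR-hsa-24,360	-2.584572467	0.000861	0.008429
piR-hsa-24,775	-2.561868282	0.002219	0.014873
piR-hsa-993	-2.425464371	0.00613	0.03002
piR-hsa-25,780	-1.484140016	0.000149	0.002478
piR-hsa-137,673	-1.288976322	0.001602	0.012488
piR-hsa-148,659	-1.273711987	0.011758	0.046786
piR-hsa-1,913,711	-1.223420061	1.5E-06	8.73E-05
piR-hsa-2106	-1.20836314	0.000927	0.00852
piR-hsa-163,380	-1.105147303	2.32E-06	9.86E-05
piR-hsa-27,622	1.024895846	0.003141	0.01846
piR-hsa-27,623	1.024895846	0.003141	0.01846
piR-hsa-727,554	1.026404197	0.009736	0.040869
piR-hsa-128,116	1.117549048	0.013188	0.04988
piR-hsa-26,508	1.141890501	0.000393	0.005182
piR-hsa-27,621	1.310886452	0.000242	0.003705
piR-hsa-28,190	1.436338019	4.39E-06	0.000165
piR-hsa-1243	1.458615974	0.001212	0.010524
piR-hsa-27,620	1.656706986	9.32E-05	0.001695
piR-hsa-1242	1.685662678	0.00255	0.016238
piR-hsa-115,220	1.701160868	0.005079	0.026217
piR-hsa-57,648	1.77670514	0.007834	0.035295
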