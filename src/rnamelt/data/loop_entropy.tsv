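# loop_type	sizes	omega_closed	omega_open	dS_over_R	provenance
hairpin	3	38	8196	-5.373815349632404	enumerated
hairpin	4	236	70188	-5.6951008302054165	enumerated
hairpin	5	1397	597996	-6.059256984690225	enumerated
hairpin	6	8968	5073900	-6.338202345878247	enumerated
hairpin	7	59065	42922452	-6.588511792255658	enumerated
hairpin	8	401290	362267652	-6.805454229825008	enumerated
hairpin	9	2781037	3051900516	-7.000695915812775	enumerated
hairpin	10	19617458	25671988020	-7.17673583206169	enumerated
internal	0,0	1	144	-4.969813299576001	enumerated
internal	0,1	1	1296	-7.16703787691222	enumerated
internal	0,2	8	11376	-7.259819610363186	enumerated
internal	0,3	30	98352	-8.095110777484635	enumerated
internal	0,4	159	842256	-8.574935082798795	enumerated
internal	0,5	877	7175952	-9.009739001363004	enumerated
internal	0,6	5271	60886800	-9.354551583563037	enumerated
internal	0,7	32939	515069424	-9.657399608382548	enumerated
internal	0,8	215504	4347211824	-9.91206576670573	enumerated
internal	1,1	2	11664	-8.671115273688494	enumerated
internal	1,2	20	102384	-8.54075345582525	enumerated
internal	1,3	66	885168	-9.503877994456584	enumerated
internal	1,4	364	7580304	-9.943909994718505	enumerated
internal	1,5	1946	64583568	-10.409939308325455	enumerated
internal	1,6	11641	547981200	-10.759462909506222	enumerated
internal	1,7	72007	4635624816	-11.072518215267857	enumerated
internal	2,2	69	898704	-9.474602499912784	enumerated
internal	2,3	227	7769808	-10.44080599413241	enumerated
internal	2,4	1255	66538224	-10.878396285920164	enumerated
internal	2,5	6669	566900208	-11.350468643569902	enumerated
internal	2,6	39919	4810057200	-11.699367132873824	enumerated
internal	3,3	1065	67174416	-11.052072940574055	enumerated
internal	3,4	5892	575260848	-11.488983367007295	enumerated
internal	3,5	31287	4901175216	-11.961782898516654	enumerated
internal	4,4	26274	4926355344	-12.1415301344326	enumerated
pk_loop	0,1	1	12	-2.4849066497880004	enumerated
pk_loop	0,2	0	12	unformable	enumerated
pk_loop	0,3	0	12	unformable	enumerated
pk_loop	0,4	0	12	unformable	enumerated
pk_loop	1,1	2	108	-3.9889840465642745	enumerated
pk_loop	1,2	0	108	unformable	enumerated
pk_loop	1,3	0	108	unformable	enumerated
pk_loop	1,4	0	108	unformable	enumerated
pk_loop	2,1	8	948	-4.774912960575186	enumerated
pk_loop	2,2	3	948	-5.755742213586912	enumerated
pk_loop	2,3	0	948	unformable	enumerated
pk_loop	2,4	0	948	unformable	enumerated
pk_loop	3,1	42	8196	-5.273731891075422	enumerated
pk_loop	3,2	25	8196	-5.79252568449059	enumerated
pk_loop	3,3	3	8196	-7.912789220690681	enumerated
pk_loop	3,4	0	8196	unformable	enumerated
pk_loop	4,1	227	70188	-5.733982617749623	enumerated
pk_loop	4,2	136	70188	-6.246277749494974	enumerated
pk_loop	4,3	55	70188	-7.151599449998555	enumerated
pk_loop	4,4	3	70188	-10.060320346562916	enumerated
pk_loop	5,1	1418	597996	-6.044336636855114	enumerated
pk_loop	5,2	998	597996	-6.395586067635723	enumerated
pk_loop	5,3	429	597996	-7.23988242501917	enumerated
pk_loop	5,4	98	597996	-8.716371865276615	enumerated
pk_loop	6,1	8896	5073900	-6.346263294139879	enumerated
pk_loop	6,2	6496	5073900	-6.660678428788729	enumerated
pk_loop	6,3	3552	5073900	-7.264354206518182	enumerated
pk_loop	6,4	1162	5073900	-8.381722373218386	enumerated
pk_loop	7,1	59310	42922452	-6.584372398805506	enumerated
pk_loop	7,2	45840	42922452	-6.841993252249657	enumerated
pk_loop	7,3	26989	42922452	-7.371720949072165	enumerated
pk_loop	7,4	11243	42922452	-8.247404611888518	enumerated
pk_loop	8,1	400386	362267652	-6.807709505979379	enumerated
pk_loop	8,2	319233	362267652	-7.034217344083589	enumerated
pk_loop	8,3	205708	362267652	-7.473680900281842	enumerated
pk_loop	8,4	99109	362267652	-8.203918333205687	enumerated
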