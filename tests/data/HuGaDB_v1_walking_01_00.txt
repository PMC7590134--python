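#Activity	walking
#ActivityID	1
#Date-Time	2026-09-24	12:00:00
acc_rf_x	acc_rf_y	acc_rf_z	gyro_rf_x	gyro_rf_y	gyro_rf_z	acc_rs_x	acc_rs_y	acc_rs_z	gyro_rs_x	gyro_rs_y	gyro_rs_z	acc_rt_x	acc_rt_y	acc_rt_z	gyro_rt_x	gyro_rt_y	gyro_rt_z	acc_lf_x	acc_lf_y	acc_lf_z	gyro_lf_x	gyro_lf_y	gyro_lf_z	acc_ls_x	acc_ls_y	acc_ls_z	gyro_ls_x	gyro_ls_y	gyro_ls_z	acc_lt_x	acc_lt_y	acc_lt_z	gyro_lt_x	gyro_lt_y	gyro_lt_z	EMG_r	EMG_l
-310	-1042	-1033	-825	86	356	393	48	1043	-1100	-545	305	-561	10	-1096	519	-484	-646	219	-384	138	-157	427	807	1033	-791	691	1072	-373	-206	347	780	-110	969	3	-526	-1191	-813
-1045	-895	225	-521	-1053	-994	161	-244	-1157	-859	691	-601	408	96	945	-848	305	-903	216	949	-1125	126	1097	-278	-154	73	-669	-952	-523	506	542	586	432	930	732	-834	976	1178
402	306	-217	108	125	882	-502	960	-797	1172	-452	139	-814	708	-543	-665	41	1150	-795	-939	684	-943	1134	-567	70	-258	72	-1028	-442	-31	820	987	49	-517	-802	183	-627	802
948	-862	-742	547	-780	-390	-920	-1056	-566	-1012	205	-602	361	-126	1152	424	-710	-129	-412	-183	-56	48	-744	-651	-167	261	332	994	534	1135	-513	-159	240	-546	-1189	-1126	-438	192
276	397	58	1111	1167	586	-755	631	102	254	-1189	480	88	-1116	-129	-1020	-923	-846	-949	-281	-373	631	699	765	407	-250	-346	899	-319	863	616	-312	-1033	-125	684	993	181	-519
-32	464	-1092	600	-50	-399	-1015	-101	-608	-1197	910	650	1184	-923	-389	1009	600	-595	381	-567	-419	246	-528	-773	-152	-582	-62	-1138	-1041	-969	252	-670	135	-978	493	-303	752	-81
-475	-1139	259	-837	501	376	1052	-847	-463	-211	237	-836	578	-630	389	939	-656	89	1005	-736	134	75	-186	-711	-505	-334	-693	-733	316	-898	72	-726	-1047	-40	750	-542	3	280
655	-949	-572	-147	-1177	-1096	-739	871	652	50	-1017	1052	-782	291	714	91	540	628	-1141	160	1040	806	-614	-113	-800	1119	-1047	316	-187	1153	20	-1045	-226	114	-627	-543	830	-448
-310	527	707	-684	-1099	275	-915	-277	695	-1091	-908	-330	154	-655	-434	239	-179	-43	-599	836	887	689	-140	-442	145	-1144	230	275	-967	647	387	1079	143	1025	725	-510	-592	1148
428	-1145	996	-264	-457	165	965	-306	1129	53	-111	1021	550	-267	-1017	-1023	-832	685	1085	753	-693	106	244	907	-1101	1015	-839	888	1082	-541	-629	-1180	41	-81	-180	-162	103	501
1181	-183	-83	43	-206	-655	366	126	979	-75	629	651	-947	-434	-958	473	-58	402	-845	-912	627	-775	-452	-754	-1113	-225	-419	852	-740	-1033	-431	-576	368	248	-1122	60	712	1069
709	-1019	-554	-796	710	-61	914	-778	542	-1048	137	-180	-759	1035	-647	701	975	-352	-927	286	-664	435	-978	553	239	-922	948	220	-132	-505	96	695	475	277	-1057	115	481	43
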