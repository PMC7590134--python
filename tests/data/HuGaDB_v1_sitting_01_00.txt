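#Activity	sitting
#ActivityID	1
#Date-Time	2026-09-24	12:00:00
acc_rf_x	acc_rf_y	acc_rf_z	gyro_rf_x	gyro_rf_y	gyro_rf_z	acc_rs_x	acc_rs_y	acc_rs_z	gyro_rs_x	gyro_rs_y	gyro_rs_z	acc_rt_x	acc_rt_y	acc_rt_z	gyro_rt_x	gyro_rt_y	gyro_rt_z	acc_lf_x	acc_lf_y	acc_lf_z	gyro_lf_x	gyro_lf_y	gyro_lf_z	acc_ls_x	acc_ls_y	acc_ls_z	gyro_ls_x	gyro_ls_y	gyro_ls_z	acc_lt_x	acc_lt_y	acc_lt_z	gyro_lt_x	gyro_lt_y	gyro_lt_z	EMG_r	EMG_l
-3	33	-30	13	22	18	-32	-6	23	-8	30	28	-10	-20	27	6	-30	-8	-37	33	25	11	-25	-37	23	33	5	-20	25	-4	2	18	-38	14	-12	7	12	33
-32	-8	22	29	30	9	3	24	-3	-1	-7	27	36	21	27	-40	3	4	-9	22	27	17	36	-15	-20	32	18	-23	-40	-8	33	-38	6	-17	38	-29	-37	20
18	12	23	36	37	12	27	-35	-40	39	37	-23	26	-38	13	-23	-3	-12	-25	23	-16	19	-39	34	2	-25	-20	11	27	-30	-40	-38	-13	2	-38	-15	11	-7
-20	-26	15	39	22	35	-27	22	-39	-16	-25	29	13	26	6	-40	30	-18	-13	37	23	-18	11	20	30	-9	-21	16	5	-2	32	39	0	-25	-1	25	15	-1
17	-22	-21	6	37	-32	-32	-32	-13	17	21	-37	-22	30	15	3	-27	-38	17	-8	23	14	-34	-39	21	28	-9	22	-16	33	-6	-13	-26	24	11	-16	-25	21
34	25	-34	-37	25	-1	20	22	29	-28	-17	18	-14	11	13	35	-34	23	0	-8	13	-18	-17	-8	17	-19	-39	17	32	38	12	27	39	20	1	-23	-12	34
2	-6	-13	-28	-17	-7	26	34	-28	33	-32	39	-22	-25	4	21	-36	27	-1	-8	15	-14	-38	-17	35	16	2	-26	8	24	-5	9	-36	-15	-23	-15	-8	1
-33	18	-20	-4	8	-15	15	7	-8	-20	-4	-12	24	1	-21	10	24	-16	-30	31	-9	11	-33	10	-30	32	12	-20	40	33	18	-24	33	-38	0	-33	37	0
-24	3	-18	10	-35	29	-24	20	-1	26	13	30	-2	-11	35	30	11	34	-10	25	-40	-37	7	-14	-24	-8	30	-37	-36	13	-27	3	-32	-12	12	23	-24	32
-8	25	31	-9	23	-26	-40	-35	15	19	26	5	26	13	21	-15	-36	-8	28	27	14	33	18	24	-30	22	9	16	-32	-3	-37	8	-28	-25	40	-1	9	20
-38	-36	-27	6	11	-10	20	-29	37	-19	-25	38	-34	34	30	-14	-27	-30	18	-8	21	-33	15	18	-7	-24	-40	-39	-30	14	-26	18	14	11	7	2	-13	-9
6	-12	-23	35	-17	-38	18	6	-8	-31	18	-5	-34	20	-40	-20	19	-18	-9	10	27	-10	14	-38	9	-37	-15	30	36	-1	-18	-30	-22	37	6	14	30	-29
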