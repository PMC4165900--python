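name	lobe	hemisphere	x	y	z
Precentral_L	frontal	L	-42	33	54
Precentral_R	frontal	R	21	51	-13
Frontal_Sup_L	frontal	L	-12	27	6
Frontal_Sup_R	frontal	R	40	29	-12
Frontal_Sup_Orb_L	frontal	L	-29	31	35
Frontal_Sup_Orb_R	frontal	R	27	8	28
Frontal_Mid_L	frontal	L	-42	57	60
Frontal_Mid_R	frontal	R	12	42	24
Frontal_Mid_Orb_L	frontal	L	-35	34	30
Frontal_Mid_Orb_R	frontal	R	21	47	39
Frontal_Inf_Oper_L	frontal	L	-26	49	20
Frontal_Inf_Oper_R	frontal	R	45	54	12
Frontal_Inf_Tri_L	frontal	L	-48	40	30
Frontal_Inf_Tri_R	frontal	R	32	7	22
Frontal_Inf_Orb_L	frontal	L	-53	7	39
Frontal_Inf_Orb_R	frontal	R	13	25	59
Rolandic_Oper_L	frontal	L	-49	25	47
Rolandic_Oper_R	frontal	R	24	14	45
Supp_Motor_Area_L	frontal	L	-39	53	44
Supp_Motor_Area_R	frontal	R	22	33	11
Olfactory_L	frontal	L	-6	8	23
Olfactory_R	frontal	R	26	46	-2
Frontal_Sup_Medial_L	frontal	L	-20	53	38
Frontal_Sup_Medial_R	frontal	R	16	61	40
Frontal_Med_Orb_L	frontal	L	-29	16	55
Frontal_Med_Orb_R	frontal	R	41	53	54
Rectus_L	frontal	L	-51	32	25
Rectus_R	frontal	R	39	13	5
Insula_L	insula	L	-34	11	1
Insula_R	insula	R	41	8	6
Cingulum_Ant_L	limbic	L	-9	-20	23
Cingulum_Ant_R	limbic	R	20	29	12
Cingulum_Mid_L	limbic	L	-16	-49	-5
Cingulum_Mid_R	limbic	R	6	19	-5
Cingulum_Post_L	limbic	L	-11	17	33
Cingulum_Post_R	limbic	R	22	-12	2
Hippocampus_L	limbic	L	-21	-40	8
Hippocampus_R	limbic	R	17	0	-8
ParaHippocampal_L	limbic	L	-7	-17	28
ParaHippocampal_R	limbic	R	10	36	-5
Amygdala_L	limbic	L	-22	-4	-11
Amygdala_R	limbic	R	13	-46	29
Calcarine_L	occipital	L	-43	-80	-1
Calcarine_R	occipital	R	38	-66	-2
Cuneus_L	occipital	L	-30	-64	24
Cuneus_R	occipital	R	32	-62	2
Lingual_L	occipital	L	-7	-98	19
Lingual_R	occipital	R	20	-64	30
Occipital_Sup_L	occipital	L	-14	-74	-4
Occipital_Sup_R	occipital	R	9	-97	20
Occipital_Mid_L	occipital	L	-26	-79	33
Occipital_Mid_R	occipital	R	19	-76	3
Occipital_Inf_L	occipital	L	-44	-78	-6
Occipital_Inf_R	occipital	R	10	-82	7
Fusiform_L	occipital	L	-11	-84	31
Fusiform_R	occipital	R	29	-73	27
Postcentral_L	parietal	L	-32	-75	35
Postcentral_R	parietal	R	35	-30	24
Parietal_Sup_L	parietal	L	-30	-74	69
Parietal_Sup_R	parietal	R	45	-72	50
Parietal_Inf_L	parietal	L	-45	-79	55
Parietal_Inf_R	parietal	R	49	-65	66
SupraMarginal_L	parietal	L	-44	-41	51
SupraMarginal_R	parietal	R	35	-63	44
Angular_L	parietal	L	-53	-32	40
Angular_R	parietal	R	45	-60	25
Precuneus_L	parietal	L	-11	-54	62
Precuneus_R	parietal	R	52	-32	54
Paracentral_Lobule_L	parietal	L	-55	-26	62
Paracentral_Lobule_R	parietal	R	29	-76	28
Caudate_L	subcortical	L	-14	10	14
Caudate_R	subcortical	R	27	11	-10
Putamen_L	subcortical	L	-24	5	-4
Putamen_R	subcortical	R	23	7	-4
Pallidum_L	subcortical	L	-20	-13	9
Pallidum_R	subcortical	R	24	-21	-6
Thalamus_L	subcortical	L	-18	8	14
Thalamus_R	subcortical	R	6	-10	17
Heschl_L	temporal	L	-46	1	-2
Heschl_R	temporal	R	39	-11	-7
Temporal_Sup_L	temporal	L	-37	13	7
Temporal_Sup_R	temporal	R	54	-43	10
Temporal_Pole_Sup_L	temporal	L	-49	-3	-3
Temporal_Pole_Sup_R	temporal	R	58	-37	-10
Temporal_Mid_L	temporal	L	-56	-13	6
Temporal_Mid_R	temporal	R	38	15	-31
Temporal_Pole_Mid_L	temporal	L	-56	-38	-4
Temporal_Pole_Mid_R	temporal	R	42	-5	-27
Temporal_Inf_L	temporal	L	-44	8	-11
Temporal_Inf_R	temporal	R	41	-31	-1
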