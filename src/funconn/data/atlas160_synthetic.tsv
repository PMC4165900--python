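name	lobe	hemisphere	x	y	z
default_00	default	R	5	63	14
default_01	default	L	-22	38	49
default_02	default	R	21	27	25
default_03	default	L	-18	9	1
default_04	default	R	6	10	47
default_05	default	R	49	49	18
default_06	default	L	-43	17	-8
default_07	default	R	26	52	19
default_08	default	L	-8	46	11
default_09	default	R	26	27	31
default_10	default	L	-54	36	48
default_11	default	R	6	27	57
default_12	default	R	33	31	4
default_13	default	R	5	24	35
default_14	default	L	-10	50	53
default_15	default	L	-45	46	32
default_16	default	R	16	64	-14
default_17	default	R	55	53	39
default_18	default	R	16	48	-14
default_19	default	R	21	12	42
default_20	default	L	-39	50	26
default_21	default	R	31	55	41
default_22	default	L	-30	33	44
default_23	default	R	17	57	-6
default_24	default	R	47	27	0
default_25	default	R	29	60	43
default_26	default	R	34	22	32
default_27	default	R	17	57	-11
default_28	default	L	-43	49	54
default_29	default	L	-31	32	4
default_30	default	L	-9	49	54
default_31	default	R	21	19	3
default_32	default	L	-8	37	20
default_33	default	R	26	26	0
fronto_parietal_00	fronto_parietal	R	5	-56	34
fronto_parietal_01	fronto_parietal	R	48	-62	44
fronto_parietal_02	fronto_parietal	R	46	-67	42
fronto_parietal_03	fronto_parietal	R	21	-62	23
fronto_parietal_04	fronto_parietal	L	-44	-68	70
fronto_parietal_05	fronto_parietal	L	-40	-37	22
fronto_parietal_06	fronto_parietal	R	31	-76	28
fronto_parietal_07	fronto_parietal	R	37	-75	50
fronto_parietal_08	fronto_parietal	L	-10	-54	52
fronto_parietal_09	fronto_parietal	L	-53	-57	68
fronto_parietal_10	fronto_parietal	L	-47	-59	28
fronto_parietal_11	fronto_parietal	L	-26	-27	42
fronto_parietal_12	fronto_parietal	L	-9	-25	42
fronto_parietal_13	fronto_parietal	R	20	-62	45
fronto_parietal_14	fronto_parietal	R	38	-44	31
fronto_parietal_15	fronto_parietal	R	12	-68	38
fronto_parietal_16	fronto_parietal	R	33	-67	22
fronto_parietal_17	fronto_parietal	L	-51	-62	47
fronto_parietal_18	fronto_parietal	L	-9	-71	61
fronto_parietal_19	fronto_parietal	R	20	-43	28
fronto_parietal_20	fronto_parietal	R	34	-56	41
cingulo_opercular_00	cingulo_opercular	L	-27	28	30
cingulo_opercular_01	cingulo_opercular	R	20	-44	33
cingulo_opercular_02	cingulo_opercular	L	-29	12	19
cingulo_opercular_03	cingulo_opercular	L	-30	39	4
cingulo_opercular_04	cingulo_opercular	R	25	40	-11
cingulo_opercular_05	cingulo_opercular	L	-3	-24	11
cingulo_opercular_06	cingulo_opercular	L	-5	-25	24
cingulo_opercular_07	cingulo_opercular	R	25	15	13
cingulo_opercular_08	cingulo_opercular	R	26	26	18
cingulo_opercular_09	cingulo_opercular	R	27	10	11
cingulo_opercular_10	cingulo_opercular	L	-25	22	11
cingulo_opercular_11	cingulo_opercular	L	-9	15	3
cingulo_opercular_12	cingulo_opercular	R	26	-7	10
cingulo_opercular_13	cingulo_opercular	R	25	-33	-14
cingulo_opercular_14	cingulo_opercular	L	-30	-36	13
cingulo_opercular_15	cingulo_opercular	L	-11	-27	28
cingulo_opercular_16	cingulo_opercular	R	19	-21	22
cingulo_opercular_17	cingulo_opercular	L	-24	-21	7
cingulo_opercular_18	cingulo_opercular	R	13	13	-1
cingulo_opercular_19	cingulo_opercular	L	-9	-38	23
cingulo_opercular_20	cingulo_opercular	R	14	34	-5
cingulo_opercular_21	cingulo_opercular	L	-18	7	-3
cingulo_opercular_22	cingulo_opercular	L	-5	17	-14
cingulo_opercular_23	cingulo_opercular	R	6	1	11
cingulo_opercular_24	cingulo_opercular	L	-22	28	25
cingulo_opercular_25	cingulo_opercular	R	2	-33	38
cingulo_opercular_26	cingulo_opercular	L	-20	30	8
cingulo_opercular_27	cingulo_opercular	R	15	-15	-12
cingulo_opercular_28	cingulo_opercular	R	27	41	13
cingulo_opercular_29	cingulo_opercular	R	18	-44	38
cingulo_opercular_30	cingulo_opercular	L	-17	22	42
cingulo_opercular_31	cingulo_opercular	R	25	9	20
sensorimotor_00	sensorimotor	L	-37	-68	43
sensorimotor_01	sensorimotor	L	-55	-26	57
sensorimotor_02	sensorimotor	R	23	-31	66
sensorimotor_03	sensorimotor	L	-43	-59	63
sensorimotor_04	sensorimotor	L	-33	-35	26
sensorimotor_05	sensorimotor	R	37	-37	60
sensorimotor_06	sensorimotor	L	-38	-34	67
sensorimotor_07	sensorimotor	R	43	-76	31
sensorimotor_08	sensorimotor	L	-46	-71	51
sensorimotor_09	sensorimotor	R	18	-67	25
sensorimotor_10	sensorimotor	R	36	-30	62
sensorimotor_11	sensorimotor	R	54	-58	44
sensorimotor_12	sensorimotor	R	28	-64	21
sensorimotor_13	sensorimotor	L	-17	-69	60
sensorimotor_14	sensorimotor	R	15	-80	22
sensorimotor_15	sensorimotor	R	53	-32	57
sensorimotor_16	sensorimotor	L	-41	-80	32
sensorimotor_17	sensorimotor	R	38	-50	53
sensorimotor_18	sensorimotor	L	-18	-78	58
sensorimotor_19	sensorimotor	R	30	-32	55
sensorimotor_20	sensorimotor	L	-7	-50	35
sensorimotor_21	sensorimotor	L	-31	-58	66
sensorimotor_22	sensorimotor	R	20	-62	50
sensorimotor_23	sensorimotor	R	13	-50	38
sensorimotor_24	sensorimotor	L	-25	-40	63
sensorimotor_25	sensorimotor	R	13	-52	22
sensorimotor_26	sensorimotor	R	17	-25	27
sensorimotor_27	sensorimotor	R	5	-68	63
sensorimotor_28	sensorimotor	L	-28	-68	30
sensorimotor_29	sensorimotor	L	-24	-70	38
sensorimotor_30	sensorimotor	R	44	-39	67
sensorimotor_31	sensorimotor	L	-9	-67	42
sensorimotor_32	sensorimotor	L	-20	-62	22
occipital_00	occipital	R	34	-82	-3
occipital_01	occipital	R	10	-75	-12
occipital_02	occipital	R	45	-58	2
occipital_03	occipital	L	-34	-61	29
occipital_04	occipital	L	-19	-75	-7
occipital_05	occipital	R	24	-62	13
occipital_06	occipital	R	13	-94	23
occipital_07	occipital	L	-20	-98	23
occipital_08	occipital	L	-25	-92	18
occipital_09	occipital	L	-24	-77	23
occipital_10	occipital	R	28	-66	-10
occipital_11	occipital	L	-35	-87	17
occipital_12	occipital	L	-26	-63	-1
occipital_13	occipital	L	-42	-84	10
occipital_14	occipital	R	26	-76	26
occipital_15	occipital	L	-20	-62	-11
occipital_16	occipital	R	17	-65	26
occipital_17	occipital	R	13	-74	2
occipital_18	occipital	R	18	-61	1
occipital_19	occipital	L	-33	-91	-15
occipital_20	occipital	L	-25	-89	1
occipital_21	occipital	R	6	-76	-1
cerebellum_00	cerebellum	R	20	-81	-44
cerebellum_01	cerebellum	L	-32	-61	-42
cerebellum_02	cerebellum	L	-35	-74	-31
cerebellum_03	cerebellum	L	-7	-64	-39
cerebellum_04	cerebellum	L	-25	-65	-17
cerebellum_05	cerebellum	L	-29	-61	-19
cerebellum_06	cerebellum	R	32	-53	-39
cerebellum_07	cerebellum	L	-29	-82	-41
cerebellum_08	cerebellum	R	10	-83	-31
cerebellum_09	cerebellum	L	-33	-52	-34
cerebellum_10	cerebellum	L	-2	-68	-44
cerebellum_11	cerebellum	L	-36	-79	-28
cerebellum_12	cerebellum	R	20	-62	-26
cerebellum_13	cerebellum	R	24	-58	-21
cerebellum_14	cerebellum	R	39	-78	-20
cerebellum_15	cerebellum	L	-27	-61	-30
cerebellum_16	cerebellum	L	-32	-70	-36
cerebellum_17	cerebellum	L	-25	-47	-36
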