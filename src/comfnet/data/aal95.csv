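code,name,hemisphere,lobe
2001,Precentral_L,L,Lateral frontal
2002,Precentral_R,R,Lateral frontal
2101,Frontal_Sup_L,L,Lateral frontal
2102,Frontal_Sup_R,R,Lateral frontal
2111,Frontal_Sup_Orb_L,L,Lateral frontal
2112,Frontal_Sup_Orb_R,R,Lateral frontal
2201,Frontal_Mid_L,L,Lateral frontal
2202,Frontal_Mid_R,R,Lateral frontal
2211,Frontal_Mid_Orb_L,L,Lateral frontal
2212,Frontal_Mid_Orb_R,R,Lateral frontal
2301,Frontal_Inf_Oper_L,L,Lateral frontal
2302,Frontal_Inf_Oper_R,R,Lateral frontal
2311,Frontal_Inf_Tri_L,L,Lateral frontal
2312,Frontal_Inf_Tri_R,R,Lateral frontal
2321,Frontal_Inf_Orb_L,L,Lateral frontal
2322,Frontal_Inf_Orb_R,R,Lateral frontal
2331,Rolandic_Oper_L,L,Lateral frontal
2332,Rolandic_Oper_R,R,Lateral frontal
2401,Supp_Motor_Area_L,L,Medial frontal
2402,Supp_Motor_Area_R,R,Medial frontal
2501,Olfactory_L,L,Medial frontal
2502,Olfactory_R,R,Medial frontal
2601,Frontal_Sup_Medial_L,L,Medial frontal
2602,Frontal_Sup_Medial_R,R,Medial frontal
2611,Frontal_Med_Orb_L,L,Medial frontal
2612,Frontal_Med_Orb_R,R,Medial frontal
2701,Rectus_L,L,Medial frontal
2702,Rectus_R,R,Medial frontal
3001,Insula_L,L,Insula
3002,Insula_R,R,Insula
4001,Cingulum_Ant_L,L,Limbic
4002,Cingulum_Ant_R,R,Limbic
4011,Cingulum_Mid_L,L,Limbic
4012,Cingulum_Mid_R,R,Limbic
4021,Cingulum_Post_L,L,Limbic
4022,Cingulum_Post_R,R,Limbic
4101,Hippocampus_L,L,Hippocampus+Amygdala
4102,Hippocampus_R,R,Hippocampus+Amygdala
4111,ParaHippocampal_L,L,Hippocampus+Amygdala
4112,ParaHippocampal_R,R,Hippocampus+Amygdala
4201,Amygdala_L,L,Hippocampus+Amygdala
4202,Amygdala_R,R,Hippocampus+Amygdala
5001,Calcarine_L,L,Occipital
5002,Calcarine_R,R,Occipital
5011,Cuneus_L,L,Occipital
5012,Cuneus_R,R,Occipital
5021,Lingual_L,L,Occipital
5022,Lingual_R,R,Occipital
5101,Occipital_Sup_L,L,Occipital
5102,Occipital_Sup_R,R,Occipital
5201,Occipital_Mid_L,L,Occipital
5202,Occipital_Mid_R,R,Occipital
5301,Occipital_Inf_L,L,Occipital
5302,Occipital_Inf_R,R,Occipital
5401,Fusiform_L,L,Parietal
5402,Fusiform_R,R,Parietal
6001,Postcentral_L,L,Parietal
6002,Postcentral_R,R,Parietal
6101,Parietal_Sup_L,L,Parietal
6102,Parietal_Sup_R,R,Parietal
6201,Parietal_Inf_L,L,Parietal
6202,Parietal_Inf_R,R,Parietal
6211,SupraMarginal_L,L,Parietal
6212,SupraMarginal_R,R,Parietal
6221,Angular_L,L,Parietal
6222,Angular_R,R,Parietal
6301,Precuneus_L,L,Parietal
6302,Precuneus_R,R,Parietal
6401,Paracentral_Lobule_L,L,Parietal
6402,Paracentral_Lobule_R,R,Parietal
7001,Caudate_L,L,Subcortical
7002,Caudate_R,R,Subcortical
7011,Putamen_L,L,Subcortical
7012,Putamen_R,R,Subcortical
7021,Pallidum_L,L,Subcortical
7022,Pallidum_R,R,Subcortical
7101,Thalamus_L,L,Subcortical
7102,Thalamus_R,R,Subcortical
8101,Heschl_L,L,Temporal
8102,Heschl_R,R,Temporal
8111,Temporal_Sup_L,L,Temporal
8112,Temporal_Sup_R,R,Temporal
8121,Temporal_Pole_Sup_L,L,Temporal
8122,Temporal_Pole_Sup_R,R,Temporal
8201,Temporal_Mid_L,L,Temporal
8202,Temporal_Mid_R,R,Temporal
8211,Temporal_Pole_Mid_L,L,Temporal
8212,Temporal_Pole_Mid_R,R,Temporal
8301,Temporal_Inf_L,L,Temporal
8302,Temporal_Inf_R,R,Temporal
9001,Cerebelum_Crus1_L,L,Cerebellum
9002,Cerebelum_Crus1_R,R,Cerebellum
9011,Cerebelum_Crus2_L,L,Cerebellum
9012,Cerebelum_Crus2_R,R,Cerebellum
9100,Vermis_1_2,M,Cerebellum
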