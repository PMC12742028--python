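raw_label	merged_label
Precentral_L	Precentral_L
Precentral_R	Precentral_R
Frontal_Sup_L	Frontal_Sup_L
Frontal_Sup_R	Frontal_Sup_R
Frontal_Sup_Orb_L	Frontal_Sup_L
Frontal_Sup_Orb_R	Frontal_Sup_R
Frontal_Mid_L	Frontal_Mid_L
Frontal_Mid_R	Frontal_Mid_R
Frontal_Mid_Orb_L	Frontal_Mid_L
Frontal_Mid_Orb_R	Frontal_Mid_R
Frontal_Inf_Oper_L	Frontal_Inf_L
Frontal_Inf_Oper_R	Frontal_Inf_R
Frontal_Inf_Tri_L	Frontal_Inf_L
Frontal_Inf_Tri_R	Frontal_Inf_R
Frontal_Inf_Orb_L	Frontal_Inf_L
Frontal_Inf_Orb_R	Frontal_Inf_R
Rolandic_Oper_L	Rolandic_Oper_L
Rolandic_Oper_R	Rolandic_Oper_R
Supp_Motor_Area_L	Supp_Motor_Area_L
Supp_Motor_Area_R	Supp_Motor_Area_R
Olfactory_L	Rectus_L
Olfactory_R	Rectus_R
Frontal_Sup_Medial_L	Frontal_Med_L
Frontal_Sup_Medial_R	Frontal_Med_R
Frontal_Med_Orb_L	Frontal_Med_L
Frontal_Med_Orb_R	Frontal_Med_R
Rectus_L	Rectus_L
Rectus_R	Rectus_R
Insula_L	Insula_L
Insula_R	Insula_R
Cingulum_Ant_L	Cingulum_Ant_L
Cingulum_Ant_R	Cingulum_Ant_R
Cingulum_Mid_L	Cingulum_Mid_L
Cingulum_Mid_R	Cingulum_Mid_R
Cingulum_Post_L	Cingulum_Post_L
Cingulum_Post_R	Cingulum_Post_R
Hippocampus_L	Hippocampus_ParaHipp_L
Hippocampus_R	Hippocampus_ParaHipp_R
ParaHippocampal_L	Hippocampus_ParaHipp_L
ParaHippocampal_R	Hippocampus_ParaHipp_R
Amygdala_L	Amygdala_L
Amygdala_R	Amygdala_R
Calcarine_L	Calcarine_L
Calcarine_R	Calcarine_R
Cuneus_L	Cuneus_L
Cuneus_R	Cuneus_R
Lingual_L	Lingual_L
Lingual_R	Lingual_R
Occipital_Sup_L	Occipital_L
Occipital_Sup_R	Occipital_R
Occipital_Mid_L	Occipital_L
Occipital_Mid_R	Occipital_R
Occipital_Inf_L	Occipital_L
Occipital_Inf_R	Occipital_R
Fusiform_L	Fusiform_L
Fusiform_R	Fusiform_R
Postcentral_L	Postcentral_L
Postcentral_R	Postcentral_R
Parietal_Sup_L	Parietal_L
Parietal_Sup_R	Parietal_R
Parietal_Inf_L	Parietal_L
Parietal_Inf_R	Parietal_R
SupraMarginal_L	SupraMarginal_L
SupraMarginal_R	SupraMarginal_R
Angular_L	Angular_L
Angular_R	Angular_R
Precuneus_L	Precuneus_L
Precuneus_R	Precuneus_R
Paracentral_Lobule_L	Paracentral_Lobule_L
Paracentral_Lobule_R	Paracentral_Lobule_R
Caudate_L	Basal_Ganglia_L
Caudate_R	Basal_Ganglia_R
Putamen_L	Basal_Ganglia_L
Putamen_R	Basal_Ganglia_R
Pallidum_L	Basal_Ganglia_L
Pallidum_R	Basal_Ganglia_R
Thalamus_L	Thalamus_L
Thalamus_R	Thalamus_R
Heschl_L	Temporal_Sup_L
Heschl_R	Temporal_Sup_R
Temporal_Sup_L	Temporal_Sup_L
Temporal_Sup_R	Temporal_Sup_R
Temporal_Pole_Sup_L	Temporal_Pole_L
Temporal_Pole_Sup_R	Temporal_Pole_R
Temporal_Mid_L	Temporal_Mid_L
Temporal_Mid_R	Temporal_Mid_R
Temporal_Pole_Mid_L	Temporal_Pole_L
Temporal_Pole_Mid_R	Temporal_Pole_R
Temporal_Inf_L	Temporal_Inf_L
Temporal_Inf_R	Temporal_Inf_R
Cerebelum_Crus1_L	EXCLUDE
Cerebelum_Crus1_R	EXCLUDE
Cerebelum_Crus2_L	EXCLUDE
Cerebelum_Crus2_R	EXCLUDE
Cerebelum_3_L	EXCLUDE
Cerebelum_3_R	EXCLUDE
Cerebelum_4_5_L	EXCLUDE
Cerebelum_4_5_R	EXCLUDE
Cerebelum_6_L	EXCLUDE
Cerebelum_6_R	EXCLUDE
Cerebelum_7b_L	EXCLUDE
Cerebelum_7b_R	EXCLUDE
Cerebelum_8_L	EXCLUDE
Cerebelum_8_R	EXCLUDE
Cerebelum_9_L	EXCLUDE
Cerebelum_9_R	EXCLUDE
Cerebelum_10_L	EXCLUDE
Cerebelum_10_R	EXCLUDE
Vermis_1_2	EXCLUDE
Vermis_3	EXCLUDE
Vermis_4_5	EXCLUDE
Vermis_6	EXCLUDE
Vermis_7	EXCLUDE
Vermis_8	EXCLUDE
Vermis_9	EXCLUDE
Vermis_10	EXCLUDE
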