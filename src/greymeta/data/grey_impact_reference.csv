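study_type,review_id,group,title,n_studies_with,n_studies_without,pct_studies_lost_printed,n_participants_with,n_participants_without,pct_participants_lost_printed,measure,with_point,with_low,with_high,without_point,without_low,without_high,pct_change_point_printed,pct_change_ci_width_printed,category_printed,sig_flip_printed
non_english,CD000980,ARI,Vitamin C for the common cold,29,26,10.3,11306,10899,3.6,RR,0.95,0.92,0.98,0.96,0.93,0.99,1.1,0.0,Negligible,none
non_english,CD003123,ARI,Epinephrine for bronchiolitis,6,5,16.7,995,965,3.0,RR,0.67,0.50,0.89,0.68,0.51,0.91,1.5,2.6,Negligible,none
non_english,CD007498,ARI,Procalcitonin to guide antibiotics in ARI,14,13,7.1,4211,4168,1.0,OR,0.91,0.70,1.19,0.90,0.69,1.19,1.1,2.0,Negligible,none
non_english,CD004974,ARI,Immunostimulants for preventing ARI in children,35,23,34.3,4060,2866,29.4,MD,-1.24,-1.54,-0.94,-1.27,-1.57,-0.96,2.4,1.7,Negligible,none
non_english,CD001266,ARI,Bronchodilators for bronchiolitis,24,23,4.2,1182,1149,2.8,MD,-0.45,-0.96,0.05,-0.41,-0.97,0.14,8.9,9.9,Small,none
non_english,CD001955,ARI,Glucocorticoids for croup,14,13,7.1,1031,998,3.2,SMD,-0.59,-0.83,-0.35,-0.65,-0.89,-0.41,10.1,0.0,Small,none
non_english,CD001954,ARI,Azithromycin for acute lower RTI,15,14,6.7,2496,2446,2.0,RR,1.09,0.64,1.85,1.03,0.60,1.78,5.5,2.5,Small,none
non_english,CD008115,ARI,Systemic corticosteroids for acute sinusitis,4,2,50.0,869,459,47.2,RR,1.40,1.08,1.81,1.18,1.05,1.34,15.7,60.3,Moderate,none
non_english,CD000247,ARI,Antibiotics for the common cold,6,5,16.7,1047,979,6.5,RR,0.95,0.59,1.51,1.11,0.70,1.76,16.8,15.2,Moderate,none
non_english,CD003124,ARI,Acetylcysteine and carbocysteine for acute RTI,3,0,100,1390,0,100,RD,-0.05,-0.12,0.02,,,,NA,NA,Substantial,NA
non_english,CD004559,ARI,Chinese medicinal herbs for influenza,2,0,100,1970,0,100,RR,1.32,0.87,2.00,,,,NA,NA,Substantial,NA
non_english,CD006198,ID,Vaccines for preventing malaria,3,2,33.3,307,237,22.8,RR,1.05,0.82,1.35,1.05,0.82,1.35,0,0,Negligible,none
non_english,CD003048,ID,Probiotics for acute infectious diarrhoea,35,34,2.9,4555,4414,3.1,MD,-24.76,-33.61,-15.91,-25.53,-34.58,-16.49,3.1,1.1,Negligible,none
non_english,CD003341,ID,High first dose quinine for severe malaria,3,2,33.3,144,72,50.0,RR,0.62,0.19,2.04,0.43,0.09,2.05,30.7,5.9,Large,none
non_english,CD004390,ID,Oral versus intravenous rehydration,18,15,16.7,1811,1436,20.7,RD,0.04,0.01,0.07,0.02,0.00,0.04,50.0,33.3,Large,lost
unpublished,CD004405,ARI,Corticosteroids for acute bacterial meningitis,25,24,4.0,4121,4036,2.1,RR,0.90,0.80,1.01,0.90,0.80,1.01,0,0,Negligible,none
unpublished,CD000980,ARI,Vitamin C for the common cold,29,27,6.9,11306,11244,0.5,RR,0.95,0.92,0.98,0.95,0.93,0.98,0,16.7,Negligible,none
unpublished,CD002744,ARI,Neuraminidase inhibitors for influenza in children,2,1,50.0,585,346,40.9,RD,-0.13,-0.21,-0.05,-0.16,-0.26,-0.05,23.1,31.3,Large,none
unpublished,CD001266,ARI,Bronchodilators for bronchiolitis,24,22,8.3,1182,1113,5.8,MD,-0.45,-0.96,0.05,-0.29,-0.79,0.21,35.6,1.0,Large,none
unpublished,CD008965,ARI,Neuraminidase inhibitors for influenza,5,0,100,3713,0,100,MD,-21.29,-29.59,-12.98,,,,NA,NA,-,NA
unpublished,CD005967,ID,Artesunate versus quinine for severe malaria,8,6,25.0,7429,7198,3.1,RR,0.71,0.62,0.80,0.72,0.64,0.82,1.4,0.0,Negligible,none
unpublished,CD003048,ID,Probiotics for acute infectious diarrhoea,35,34,2.9,4555,4461,2.1,MD,-24.76,-33.61,-15.91,-23.91,-32.78,-15.03,3.4,3.5,Negligible,none
unpublished,CD001444,DPLP,Iron therapy for iron deficiency anaemia,5,4,20.0,162,128,21.0,MD,-1.25,-4.56,2.06,-1.96,-5.17,3.15,56.8,25.7,Large,none
dissertation,CD000980,ARI,Vitamin C for the common cold,29,27,6.9,11306,11244,0.5,RR,0.95,0.92,0.98,0.95,0.93,0.98,0,16.7,Negligible,none
dissertation,CD006589,ID,Oral iron supplements in malaria-endemic areas,13,11,15.4,,,NA,RR,0.99,0.90,1.09,0.95,0.86,1.05,4.0,0.0,Negligible,none
dissertation,CD006047,DPLP,Household interventions for domestic lead exposure,5,4,20.0,815,765,6.1,MD,0.02,-0.09,0.12,0.00,-0.11,0.11,-,4.8,-,none
dissertation,CD009115,DPLP,Phonics training for poor readers,10,9,10.0,683,665,2.6,SMD,0.47,0.06,0.88,0.50,0.06,0.94,6.4,7.3,Small,none
dissertation,CD004381,DPLP,Music therapy for autism spectrum disorder,2,1,50.0,,,NA,SMD,0.50,0.22,0.79,0.48,0.18,0.77,4.0,3.5,Negligible,none
dissertation,CD009085,DPLP,Intermittent iron supplementation in children,10,9,10.0,1824,1774,2.7,RR,0.51,0.37,0.72,0.53,0.38,0.73,3.9,0.0,Negligible,none
dissertation,CD005650,DPLP,Cognitive-behavioural treatment for antisocial behaviour,4,3,25.0,560,417,25.5,RR,0.87,0.61,1.25,0.84,0.55,1.28,3.5,14.1,Negligible,none
dissertation,CD002796,DPLP,Juvenile awareness programmes for delinquency,7,6,14.3,794,715,9.9,OR,1.68,1.20,2.36,1.71,1.19,2.46,1.8,9.5,Negligible,none
dissertation,CD006546,DPLP,Kinship care for maltreated children,10,5,50.0,2189,1396,36.2,SMD,-0.24,-0.35,-0.13,-0.19,-0.38,0.00,20.8,72.7,Large,lost
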