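key,label,Baseline values,Lower limits,Upper limits,Distribution
cost_enzalutamide,Enzalutamide,7795.2,6236.16,9354.24,Gamma
cost_apalutamide,Apalutamide,5420.8,4336.64,6504.96,Gamma
cost_darolutamide,Darolutamide,5535.16,4428.128,6642.192,Gamma
cost_adt,ADT,905.61,724.488,1086.732,Gamma
cost_sl_docetaxel,Docetaxel + dexamethasone + ADT,3813.51,3050.808,4576.212,Gamma
cost_sl_abiraterone,Abiraterone + methylprednisolone + ADT,1517.2868,1213.829,1820.744,Gamma
cost_sl_enzalutamide,Enzalutamide + ADT,8700.81,6960.648,10440.97,Gamma
cost_sl_apalutamide,Apalutamide + ADT,6326.41,5061.128,7591.692,Gamma
cost_followup_lab,Follow-up cost_Laboratory tests,782.13,625.704,938.556,Gamma
cost_followup_imaging,Follow-up cost_Imaging tests,394.88,352.54,438.76,Gamma
cost_supportive,Supportive treatment,2255.87,1804.696,2707.044,Gamma
cost_end_of_life,End-of-life care,16306.27,13045.02,19567.52,Gamma
cost_ae_fatigue,Fatigue,540,432,648,Gamma
cost_ae_hypertension,Hypertension,114.26,91.408,137.112,Gamma
cost_ae_rash,Rash,39.1,31.28,46.92,Gamma
cost_ae_fracture,Fracture,21500,17200,25800,Gamma
cost_ae_anemia,Anemia,271.7,217.36,326.04,Gamma
cost_ae_back_pain,Back pain,73.6,58.88,88.32,Gamma
cost_ae_ast,Elevated aspartate aminotransferase (AST),270.84,216.672,325.008,Gamma
cost_ae_alt,Elevated alanine aminotransferase (ALT),270.84,216.672,325.008,Gamma
u_rpfs,rPFS,0.76,0.68,0.84,Beta
u_pd,PD,0.68,0.61,0.75,Beta
disutil_fatigue,Fatigue,-0.115,-0.138,-0.092,Beta
disutil_hypertension,Hypertension,-0.044,-0.0528,-0.0352,Beta
disutil_rash,Rash,-0.13,-0.156,-0.104,Beta
disutil_fracture,Fracture,-0.15,-0.18,-0.12,Beta
disutil_anemia,Anemia,-0.07,-0.084,-0.056,Beta
disutil_back_pain,Back pain,-0.067,-0.0804,-0.0536,Beta
disutil_ast,Elevated aspartate aminotransferase (AST),-0.057,-0.0684,-0.0456,Beta
disutil_alt,Elevated alanine aminotransferase (ALT),-0.057,-0.0684,-0.0456,Beta
discount_rate,Discount rate,0.05,0,0.08,Beta
hr_rpfs_ave,HR_rPFS_AvE (Apa vs. Enza),0.76,0.26,2.18,Lognormal
hr_rpfs_dve,HR_rPFS_DvE (Dar vs. Enza),0.85,0.29,2.48,Lognormal
hr_os_ave,HR_OS_AvE (Apa vs. Enza),0.99,0.55,1.79,Lognormal
hr_os_dve,HR_OS_DvE (Dar vs. Enza),1.24,0.65,2.36,Lognormal
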