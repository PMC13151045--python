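speciation,name,logd_ph7.4,pbw_ph7.4,logd_ph7.9,pbw_ph7.9,cmax_mg_per_L,rfu_trout_max,twc_original_mg_per_L,twc_refined_mg_per_L,twc_ratio,noec_mg_per_L,loec_mg_per_L,twc_original_over_loec,twc_refined_over_loec
A,Meloxicam,-1.12,0.02,-1.75,0.01,0.4,29,19.94,2.01,9.91,,,,
A,Mycophenolic acid,-0.43,0.06,-0.58,0.05,1,35,15.63,0.57,27.20,0.1,0.3,52.1,1.9
A,Ketoprofen,0.24,0.20,-0.02,0.13,4.22,30,21.39,1.10,19.38,,,,
A,Indomethacin,0.38,0.25,0.02,0.14,0.025,28,0.10,0.01,15.29,,,,
A,Felbinac,0.73,0.45,0.31,0.22,0.86,0.6,1.91,6.46,0.30,,,,
A,Diclofenac,0.75,0.47,0.49,0.30,0.5,6,1.08,0.28,3.88,0.32,1.0,1.1,0.3
A,Mephenoxalone,1.1,0.84,1.1,0.84,2.85,2,3.40,1.70,2.00,,,,
A,Nimesulide,1.13,0.88,0.94,0.64,0.1,13,0.11,0.01,9.45,,,,
A,Ataluren,1.15,0.91,0.92,0.62,2,4,2.20,0.81,2.72,,,,
A,Tolbutamide,1.27,1.11,1.21,1.01,45,35,40.37,1.28,31.64,,,,
A,Ibuprofen,1.31,1.19,0.87,0.57,15,55,12.58,0.48,26.25,0.68,,18.5,0.7
A,Atorvastatin,2.01,3.87,1.66,2.15,0.0164,0.4,0.004,0.02,0.22,,,,
A,Phenylbutazone,2.26,5.89,2.14,4.81,12.5,100,2.12,0.03,81.73,,,,
A,Salinomycin,4.14,138.74,3.77,74.49,,0.4,,,,,,,
a,Olaparib,1.75,2.50,1.75,2.50,7.3,3,2.92,0.97,3.00,0.32,1.0,2.9,1.0
a,Indapamide,2.51,8.96,2.5,8.81,0.0558,1,0.006,0.01,0.98,,,,
a,Tribenoside,4.73,374.02,4.73,374.02,,0,,,,,,,
N,Bimatoprost,2.35,6.85,2.35,6.85,0.00008,2,1.17e-05,5.84e-06,2.00,,,,
N,Cilostazol,2.97,19.41,2.97,19.41,1.2,13,0.062,0.0048,13.00,,,,
c,Clomethiazole,1.58,1.88,1.58,1.88,0.1,1,0.053,0.044,1.20,,,,
c,Imiquimod,2.71,12.54,2.71,12.54,0.00032,2,2.552e-05,1.28e-05,2.00,,,,
c,Quetiapine,3.05,22.21,3.16,26.72,0.1,2,0.005,0.0019,2.41,0.1,0.32,0.01,0.01
c,Ketoconazole,4.24,164.13,4.26,169.75,4.22,12,0.026,0.002,12.41,0.006,0.025,1.03,0.08
C,Sulpiride,-1.56,0.01,-1.09,0.02,0.05,0.8,5.22,2.96,1.76,,,,
C,Zolmitriptan,-0.16,0.10,0.32,0.23,0.007,0.9,0.069,0.03,2.02,1,3.2,0.02,0.01
C,Flecainide,0.6,0.36,1.08,0.81,0.4,0.7,1.11,0.71,1.57,,,,
C,Propranolol,0.63,0.38,1.11,0.85,0.02,3,0.053,0.01,6.72,,,,
C,Prazosin,0.75,0.47,1.09,0.82,0.001,4,0.002,0.0003,7.08,,,,
C,Procyclidine,1.1,0.84,1.59,1.91,0.08,3,0.096,0.01,6.84,,,,
C,Desloratadine,1.17,0.94,1.63,2.04,0.004,0.2,0.004,0.01,0.43,,,,
C,Atomoxetine,1.78,2.63,2.26,5.89,0.16,0.2,0.061,0.14,0.45,,,,
C,Tolperisone,1.8,2.72,2.26,5.89,0.064,11,0.024,0.001,23.83,,,,
C,Clozapine,1.95,3.50,2.41,7.57,0.3,0.9,0.086,0.044,1.95,0.018,0.031,2.8,1.4
C,Haloperidol,2.27,5.99,2.64,11.15,0.005,2,0.0008,0.000,3.73,,,,
C,Levomepromazine,2.27,5.99,2.75,13.41,0.046,0.1,0.008,0.034,0.22,,,,
C,Verapamil,2.36,6.96,2.84,15.60,0.02,2,0.003,0.001,4.48,0.3,0.6,0.005,0.001
C,Perazine,2.54,9.42,2.99,20.08,0.008,1,0.0008,0.000,2.13,,,,
C,Orphenadrine,2.6,10.42,3.07,22.97,0.1,4,0.010,0.001,8.81,,,,
C,Azelastine,2.66,11.53,3.11,24.56,0.002,0.1,0.0002,0.001,0.21,,,,
C,Clomipramine,2.72,12.75,3.21,29.06,0.09,0.4,0.007,0.008,0.91,0.01,0.1,0.07,0.08
C,Fluphenazine,2.74,13.19,3.19,28.10,0.027,0,0.002,,,,,,
C,Aripiprazole,3.14,25.83,3.62,57.89,0.0273,0.3,0.001,0.002,0.67,,,,
C,Ticlopidine,3.52,48.93,3.8,78.34,0.31,2,0.006,0.002,3.20,,,,
Z,Fexofenadine,2.48,8.52,2.47,8.38,0.131,0.5,0.015,0.031,0.49,,,,
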