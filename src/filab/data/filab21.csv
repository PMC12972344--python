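analyte_id,display_name,units,sex,rule_kind,lower,upper,note
hemoglobin,Hemoglobin,g/dl,female,two_sided,11.8,15.8,
hemoglobin,Hemoglobin,g/dl,male,two_sided,12.5,17.2,
hematocrit,Hematocrit,%,female,two_sided,35,45.5,
hematocrit,Hematocrit,%,male,two_sided,37,49,
rbc,Red blood cells,Mio./pl,female,two_sided,3.85,5.2,
rbc,Red blood cells,Mio./pl,male,two_sided,4,5.65,
rdw,Red blood cell distribution width,%,female,two_sided,11.5,15,
rdw,Red blood cell distribution width,%,male,two_sided,11.5,15,
mcv,Mean corpuscular volume,fl,female,two_sided,80,101,
mcv,Mean corpuscular volume,fl,male,two_sided,80,101,
vitamin_d_125,1.25 Vitamin D,pg/ml,female,two_sided,15.2,90.1,
vitamin_d_125,1.25 Vitamin D,pg/ml,male,two_sided,15.2,90.1,
calcium,Calcium,mmol/l,female,two_sided,2.2,2.55,
calcium,Calcium,mmol/l,male,two_sided,2.2,2.55,
crp,C-reactive protein,mg/l,female,upper_only,,6,
crp,C-reactive protein,mg/l,male,upper_only,,5,
cholesterol_total,"Cholesterol, total",mg/dl,female,upper_only,,200,
cholesterol_total,"Cholesterol, total",mg/dl,male,upper_only,,200,
ldl_cholesterol,LDL Cholesterol,mg/dl,female,upper_only,,115,
ldl_cholesterol,LDL Cholesterol,mg/dl,male,upper_only,,115,
albumin,Albumin,g/l,female,two_sided,35,52,
albumin,Albumin,g/l,male,two_sided,35,52,
uric_acid,Uric acid,umol/l,female,two_sided,140,340,
uric_acid,Uric acid,umol/l,male,two_sided,200,420,
egfr,eGFR,ml/min,female,lower_only,45,,age-adjusted cutoff 45 (CKD 3a) used cohort-wide (>=70 y) instead of the standard 90; source table prints the unit as mU/min
egfr,eGFR,ml/min,male,lower_only,45,,age-adjusted cutoff 45 (CKD 3a) used cohort-wide (>=70 y) instead of the standard 90; source table prints the unit as mU/min
creatinine,Creatinine,umol/l,female,two_sided,45,84,
creatinine,Creatinine,umol/l,male,two_sided,59,104,
cholinesterase,Cholinesterase enzyme,kU/l,female,two_sided,4.26,11.25,
cholinesterase,Cholinesterase enzyme,kU/l,male,two_sided,5.32,12.92,
protein_total,"Protein, total",g/l,female,two_sided,65,80,
protein_total,"Protein, total",g/l,male,two_sided,65,80,
mch,Mean corpuscular hemoglobin,pg,female,two_sided,27,34,
mch,Mean corpuscular hemoglobin,pg,male,two_sided,27,34,
quick_value,Quick value,%,female,two_sided,70,130,
quick_value,Quick value,%,male,two_sided,70,130,
mpv,Mean platelet volume,fl,female,two_sided,8.5,11.5,
mpv,Mean platelet volume,fl,male,two_sided,8.5,11.5,
hdl_cholesterol,HDL Cholesterol,mg/dl,female,lower_only,45,,
hdl_cholesterol,HDL Cholesterol,mg/dl,male,lower_only,40,,
hba1c_mmol_mol,HbA1c,mmol/mol,female,two_sided,29,38,redundant with hba1c_percent; both retained so the panel matches the printed 44-item list
hba1c_mmol_mol,HbA1c,mmol/mol,male,two_sided,29,38,redundant with hba1c_percent; both retained so the panel matches the printed 44-item list
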