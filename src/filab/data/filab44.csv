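analyte_id,display_name,units,sex,rule_kind,lower,upper,note
potassium,Potassium,mmol/l,female,two_sided,3.7,5.1,
potassium,Potassium,mmol/l,male,two_sided,3.7,5.1,
sodium,Sodium,mmol/l,female,two_sided,135,145,
sodium,Sodium,mmol/l,male,two_sided,135,145,
phosphate,Phosphate,mmol/l,female,two_sided,0.81,1.45,
phosphate,Phosphate,mmol/l,male,two_sided,0.81,1.45,
calcium,Calcium,mmol/l,female,two_sided,2.2,2.55,
calcium,Calcium,mmol/l,male,two_sided,2.2,2.55,
crp,C-reactive protein,mg/l,female,upper_only,,6,
crp,C-reactive protein,mg/l,male,upper_only,,5,
creatinine,Creatinine,umol/l,female,two_sided,45,84,
creatinine,Creatinine,umol/l,male,two_sided,59,104,
egfr,eGFR,ml/min,female,lower_only,45,,age-adjusted cutoff 45 (CKD 3a) used cohort-wide (>=70 y) instead of the standard 90; source table prints the unit as mU/min
egfr,eGFR,ml/min,male,lower_only,45,,age-adjusted cutoff 45 (CKD 3a) used cohort-wide (>=70 y) instead of the standard 90; source table prints the unit as mU/min
amylase,Amylase,U/l,female,upper_only,,100,
amylase,Amylase,U/l,male,upper_only,,100,
ggt,Gamma-glutamyltransferase,U/l,female,upper_only,,38,
ggt,Gamma-glutamyltransferase,U/l,male,upper_only,,55,relation symbol missing in source table ("55"); encoded as <55 consistent with the female row
alkaline_phosphatase,"Phosphatase, alkaline",U/l,female,two_sided,35,104,
alkaline_phosphatase,"Phosphatase, alkaline",U/l,male,two_sided,40,129,
cholesterol_total,"Cholesterol, total",mg/dl,female,upper_only,,200,
cholesterol_total,"Cholesterol, total",mg/dl,male,upper_only,,200,
hdl_cholesterol,HDL Cholesterol,mg/dl,female,lower_only,45,,
hdl_cholesterol,HDL Cholesterol,mg/dl,male,lower_only,40,,
ldl_cholesterol,LDL Cholesterol,mg/dl,female,upper_only,,115,
ldl_cholesterol,LDL Cholesterol,mg/dl,male,upper_only,,115,
non_hdl_cholesterol,non-HDL Cholesterol,mg/dl,female,upper_only,,150,
non_hdl_cholesterol,non-HDL Cholesterol,mg/dl,male,upper_only,,150,
triglycerides,Triglycerides,mg/dl,female,upper_only,,190,
triglycerides,Triglycerides,mg/dl,male,upper_only,,190,
protein_total,"Protein, total",g/l,female,two_sided,65,80,
protein_total,"Protein, total",g/l,male,two_sided,65,80,
albumin,Albumin,g/l,female,two_sided,35,52,
albumin,Albumin,g/l,male,two_sided,35,52,
bilirubin,Bilirubin,umol/l,female,two_sided,2,21,
bilirubin,Bilirubin,umol/l,male,two_sided,2,21,
ferritin,Ferritin,ug/l,female,two_sided,27,365,
ferritin,Ferritin,ug/l,male,two_sided,27,365,
tsh,Thyroid stimulating hormone,mU/l,female,two_sided,0.27,4.2,
tsh,Thyroid stimulating hormone,mU/l,male,two_sided,0.27,4.2,
inr,International normalized ratio,ratio,female,two_sided,0.9,1.25,algebraically related to quick_value; both coded independently (the printed 44-item panel contains both)
inr,International normalized ratio,ratio,male,two_sided,0.9,1.25,algebraically related to quick_value; both coded independently (the printed 44-item panel contains both)
quick_value,Quick value,%,female,two_sided,70,130,
quick_value,Quick value,%,male,two_sided,70,130,
aptt,Activated partial thromboplastin time,sec,female,two_sided,26,36,
aptt,Activated partial thromboplastin time,sec,male,two_sided,26,36,
cholinesterase,Cholinesterase enzyme,kU/l,female,two_sided,4.26,11.25,
cholinesterase,Cholinesterase enzyme,kU/l,male,two_sided,5.32,12.92,
ast,Aspartate aminotransferase,U/l,female,upper_only,,31,
ast,Aspartate aminotransferase,U/l,male,upper_only,,35,
alt,Alanine transaminase,U/l,female,upper_only,,34,
alt,Alanine transaminase,U/l,male,upper_only,,45,relation symbol missing in source table ("45"); encoded as <45 consistent with the female row
wbc,White blood cells,10^3/uL,female,two_sided,3.6,10.5,
wbc,White blood cells,10^3/uL,male,two_sided,3.6,10.5,
rbc,Red blood cells,Mio./pl,female,two_sided,3.85,5.2,
rbc,Red blood cells,Mio./pl,male,two_sided,4,5.65,
hemoglobin,Hemoglobin,g/dl,female,two_sided,11.8,15.8,
hemoglobin,Hemoglobin,g/dl,male,two_sided,12.5,17.2,
hematocrit,Hematocrit,%,female,two_sided,35,45.5,
hematocrit,Hematocrit,%,male,two_sided,37,49,
rdw,Red blood cell distribution width,%,female,two_sided,11.5,15,
rdw,Red blood cell distribution width,%,male,two_sided,11.5,15,
mcv,Mean corpuscular volume,fl,female,two_sided,80,101,
mcv,Mean corpuscular volume,fl,male,two_sided,80,101,
mch,Mean corpuscular hemoglobin,pg,female,two_sided,27,34,
mch,Mean corpuscular hemoglobin,pg,male,two_sided,27,34,
mchc,Mean corpuscular hemoglobin concentration,g/dl,female,two_sided,31.5,36,
mchc,Mean corpuscular hemoglobin concentration,g/dl,male,two_sided,31.5,36,
platelets,Platelets,10^3/uL,female,two_sided,160,370,
platelets,Platelets,10^3/uL,male,two_sided,160,370,
platelets_gt12fl,Platelets >12fl,%,female,two_sided,15,35,
platelets_gt12fl,Platelets >12fl,%,male,two_sided,15,35,
mpv,Mean platelet volume,fl,female,two_sided,8.5,11.5,
mpv,Mean platelet volume,fl,male,two_sided,8.5,11.5,
pdw,Platelet distribution width,fl,female,two_sided,9,17,
pdw,Platelet distribution width,fl,male,two_sided,9,17,
hba1c_percent,HbA1c,%,female,two_sided,4.8,5.6,redundant with hba1c_mmol_mol (same quantity in two units); both retained so the panel matches the printed 44-item list
hba1c_percent,HbA1c,%,male,two_sided,4.8,5.6,redundant with hba1c_mmol_mol (same quantity in two units); both retained so the panel matches the printed 44-item list
hba1c_mmol_mol,HbA1c,mmol/mol,female,two_sided,29,38,redundant with hba1c_percent; both retained so the panel matches the printed 44-item list
hba1c_mmol_mol,HbA1c,mmol/mol,male,two_sided,29,38,redundant with hba1c_percent; both retained so the panel matches the printed 44-item list
vitamin_d_125,1.25 Vitamin D,pg/ml,female,two_sided,15.2,90.1,
vitamin_d_125,1.25 Vitamin D,pg/ml,male,two_sided,15.2,90.1,
bone_alkaline_phosphatase,Bone alkaline phosphatase,g/l,female,two_sided,5,27,
bone_alkaline_phosphatase,Bone alkaline phosphatase,g/l,male,two_sided,5.7,33,
ldh,Lactate dehydrogenase,U/l,female,upper_only,,248,
ldh,Lactate dehydrogenase,U/l,male,upper_only,,249,
uric_acid,Uric acid,umol/l,female,two_sided,140,340,
uric_acid,Uric acid,umol/l,male,two_sided,200,420,
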