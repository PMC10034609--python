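local_code,local_system,target_code,target_system,display
DX001,HIS-DX,U07.1,ICD-10-CM,COVID-19
DX002,HIS-DX,J12.82,ICD-10-CM,Pneumonia due to coronavirus disease 2019
DX003,HIS-DX,J96.00,ICD-10-CM,"Acute respiratory failure, unspecified whether with hypoxia or hypercapnia"
DX004,HIS-DX,J80,ICD-10-CM,Acute respiratory distress syndrome
DX005,HIS-DX,J18.9,ICD-10-CM,"Pneumonia, unspecified organism"
DX006,HIS-DX,I10,ICD-10-CM,Essential (primary) hypertension
DX007,HIS-DX,E11.9,ICD-10-CM,Type 2 diabetes mellitus without complications
DX008,HIS-DX,E78.5,ICD-10-CM,"Hyperlipidemia, unspecified"
DX009,HIS-DX,J44.9,ICD-10-CM,"Chronic obstructive pulmonary disease, unspecified"
DX010,HIS-DX,I48.91,ICD-10-CM,"Unspecified atrial fibrillation"
DX011,HIS-DX,H40.9,ICD-10-CM,Unspecified glaucoma
DX012,HIS-DX,N17.9,ICD-10-CM,"Acute kidney failure, unspecified"
DX013,HIS-DX,I50.9,ICD-10-CM,"Heart failure, unspecified"
DX014,HIS-DX,D64.9,ICD-10-CM,"Anemia, unspecified"
DX015,HIS-DX,E87.6,ICD-10-CM,Hypokalemia
DX016,HIS-DX,E87.1,ICD-10-CM,Hypo-osmolality and hyponatremia
DX017,HIS-DX,K92.2,ICD-10-CM,"Gastrointestinal hemorrhage, unspecified"
DX018,HIS-DX,N39.0,ICD-10-CM,"Urinary tract infection, site not specified"
DX019,HIS-DX,A41.9,ICD-10-CM,"Sepsis, unspecified organism"
DX020,HIS-DX,R05.9,ICD-10-CM,"Cough, unspecified"
DX021,HIS-DX,R06.02,ICD-10-CM,Shortness of breath
DX022,HIS-DX,R50.9,ICD-10-CM,"Fever, unspecified"
DX023,HIS-DX,I21.9,ICD-10-CM,"Acute myocardial infarction, unspecified"
DX024,HIS-DX,I63.9,ICD-10-CM,"Cerebral infarction, unspecified"
DX025,HIS-DX,I26.99,ICD-10-CM,Other pulmonary embolism without acute cor pulmonale
DX026,HIS-DX,I82.409,ICD-10-CM,Acute embolism and thrombosis of unspecified deep veins of unspecified lower extremity
DX027,HIS-DX,F05,ICD-10-CM,Delirium due to known physiological condition
DX028,HIS-DX,G93.1,ICD-10-CM,"Anoxic brain damage, not elsewhere classified"
DX029,HIS-DX,K70.30,ICD-10-CM,Alcoholic cirrhosis of liver without ascites
DX030,HIS-DX,N18.9,ICD-10-CM,"Chronic kidney disease, unspecified"
DX031,HIS-DX,C34.90,ICD-10-CM,"Malignant neoplasm of unspecified part of unspecified bronchus or lung"
DX032,HIS-DX,C50.919,ICD-10-CM,"Malignant neoplasm of unspecified site of unspecified female breast"
DX033,HIS-DX,D69.6,ICD-10-CM,"Thrombocytopenia, unspecified"
DX034,HIS-DX,E66.9,ICD-10-CM,"Obesity, unspecified"
DX035,HIS-DX,E03.9,ICD-10-CM,"Hypothyroidism, unspecified"
DX036,HIS-DX,F32.9,ICD-10-CM,"Major depressive disorder, single episode, unspecified"
DX037,HIS-DX,G47.33,ICD-10-CM,Obstructive sleep apnea (adult) (pediatric)
DX038,HIS-DX,M81.0,ICD-10-CM,Age-related osteoporosis without current pathological fracture
DX039,HIS-DX,K21.9,ICD-10-CM,Gastro-esophageal reflux disease without esophagitis
DX040,HIS-DX,B96.20,ICD-10-CM,"Unspecified Escherichia coli as the cause of diseases classified elsewhere"
DX041,HIS-DX,R65.20,ICD-10-CM,Severe sepsis without septic shock
DX042,HIS-DX,R57.0,ICD-10-CM,Cardiogenic shock
DX043,HIS-DX,J95.851,ICD-10-CM,Ventilator associated pneumonia
DX044,HIS-DX,L89.90,ICD-10-CM,"Pressure ulcer of unspecified site, unspecified stage"
DX045,HIS-DX,R26.81,ICD-10-CM,Unsteadiness on feet
DX046,HIS-DX,Z51.5,ICD-10-CM,Encounter for palliative care
DX047,HIS-DX,I95.9,ICD-10-CM,"Hypotension, unspecified"
DX048,HIS-DX,R41.82,ICD-10-CM,Altered mental status
DX049,HIS-DX,J45.909,ICD-10-CM,"Unspecified asthma, uncomplicated"
DX050,HIS-DX,G30.9,ICD-10-CM,"Alzheimer's disease, unspecified"
LAB01,HIS-LAB,718-7,LOINC,Hemoglobin [Mass/volume] in Blood
LAB02,HIS-LAB,6690-2,LOINC,Leukocytes [#/volume] in Blood by Automated count
LAB03,HIS-LAB,777-3,LOINC,Platelets [#/volume] in Blood by Automated count
LAB04,HIS-LAB,2160-0,LOINC,Creatinine [Mass/volume] in Serum or Plasma
LAB05,HIS-LAB,3094-0,LOINC,Urea nitrogen [Mass/volume] in Serum or Plasma
LAB06,HIS-LAB,2951-2,LOINC,Sodium [Moles/volume] in Serum or Plasma
LAB07,HIS-LAB,2823-3,LOINC,Potassium [Moles/volume] in Serum or Plasma
LAB08,HIS-LAB,1742-6,LOINC,Alanine aminotransferase [Enzymatic activity/volume] in Serum or Plasma
LAB09,HIS-LAB,1920-8,LOINC,Aspartate aminotransferase [Enzymatic activity/volume] in Serum or Plasma
LAB10,HIS-LAB,1975-2,LOINC,Bilirubin.total [Mass/volume] in Serum or Plasma
LAB11,HIS-LAB,1988-5,LOINC,C reactive protein [Mass/volume] in Serum or Plasma
LAB12,HIS-LAB,2276-4,LOINC,Ferritin [Mass/volume] in Serum or Plasma
LAB13,HIS-LAB,48065-7,LOINC,Fibrin D-dimer FEU [Mass/volume] in Platelet poor plasma
LAB14,HIS-LAB,2532-0,LOINC,Lactate dehydrogenase [Enzymatic activity/volume] in Serum or Plasma
LAB15,HIS-LAB,751-8,LOINC,Neutrophils [#/volume] in Blood by Automated count
LAB16,HIS-LAB,731-0,LOINC,Lymphocytes [#/volume] in Blood by Automated count
LAB17,HIS-LAB,2345-7,LOINC,Glucose [Mass/volume] in Serum or Plasma
LAB18,HIS-LAB,33959-8,LOINC,Procalcitonin [Mass/volume] in Serum or Plasma
LAB19,HIS-LAB,2524-7,LOINC,Lactate [Moles/volume] in Serum or Plasma
LAB20,HIS-LAB,3016-3,LOINC,Thyrotropin [Units/volume] in Serum or Plasma
OBS01,HIS-OBS,8310-5,LOINC,Body temperature
OBS02,HIS-OBS,8867-4,LOINC,Heart rate
OBS03,HIS-OBS,9279-1,LOINC,Respiratory rate
OBS04,HIS-OBS,8480-6,LOINC,Systolic blood pressure
OBS05,HIS-OBS,8462-4,LOINC,Diastolic blood pressure
OBS06,HIS-OBS,2708-6,LOINC,Oxygen saturation in Arterial blood
OBS07,HIS-OBS,29463-7,LOINC,Body weight
OBS08,HIS-OBS,8302-2,LOINC,Body height
OBS09,HIS-OBS,9269-2,LOINC,Glasgow coma score total
OBS10,HIS-OBS,3151-8,LOINC,Inhaled oxygen flow rate
DRUG01,HIS-DRUG,387517004,SNOMED CT,Paracetamol
DRUG02,HIS-DRUG,372756006,SNOMED CT,Warfarin
DRUG03,HIS-DRUG,387458008,SNOMED CT,Aspirin
DRUG04,HIS-DRUG,372584003,SNOMED CT,Enoxaparin
DRUG05,HIS-DRUG,396458002,SNOMED CT,Methylprednisolone
DRUG06,HIS-DRUG,372740001,SNOMED CT,Dexamethasone
DRUG07,HIS-DRUG,387467008,SNOMED CT,Azithromycin
DRUG08,HIS-DRUG,372809001,SNOMED CT,Ceftriaxone
DRUG09,HIS-DRUG,386864001,SNOMED CT,Remdesivir
DRUG10,HIS-DRUG,387362001,SNOMED CT,Epinephrine
DRUG11,HIS-DRUG,387560008,SNOMED CT,Midazolam
DRUG12,HIS-DRUG,373134008,SNOMED CT,Propofol
PROC01,HIS-PROC,40617009,SNOMED CT,Artificial ventilation
PROC02,HIS-PROC,112798008,SNOMED CT,Insertion of catheter into peripheral vein
PROC03,HIS-PROC,265764009,SNOMED CT,Renal dialysis
PROC04,HIS-PROC,71388002,SNOMED CT,Procedure
PROC05,HIS-PROC,168731009,SNOMED CT,Plain chest X-ray
LLST01,HIS-LLST,304253006,SNOMED CT,Not for resuscitation
LLST02,HIS-LLST,186073009,SNOMED CT,Do not intubate
LLST03,HIS-LLST,735324008,SNOMED CT,Treatment escalation plan
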