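[
  {"code": "NA", "name": "not available"},
  {"code": "A41.9", "name": "sepsis, unspecified organism"},
  {"code": "B18.2", "name": "chronic viral hepatitis C"},
  {"code": "C15.9", "name": "malignant neoplasm of oesophagus, unspecified"},
  {"code": "C16.9", "name": "malignant neoplasm of stomach, unspecified"},
  {"code": "C18.9", "name": "malignant neoplasm of colon, unspecified"},
  {"code": "C20", "name": "malignant neoplasm of rectum"},
  {"code": "C22.0", "name": "liver cell carcinoma"},
  {"code": "C22.1", "name": "intrahepatic bile duct carcinoma"},
  {"code": "C25.9", "name": "malignant neoplasm of pancreas, unspecified"},
  {"code": "C34.9", "name": "malignant neoplasm of bronchus or lung, unspecified"},
  {"code": "C43.9", "name": "malignant melanoma of skin, unspecified"},
  {"code": "C45.0", "name": "mesothelioma of pleura"},
  {"code": "C50.9", "name": "malignant neoplasm of breast, unspecified"},
  {"code": "C56", "name": "malignant neoplasm of ovary"},
  {"code": "C61", "name": "malignant neoplasm of prostate"},
  {"code": "C64.9", "name": "malignant neoplasm of kidney, except renal pelvis"},
  {"code": "C67.9", "name": "malignant neoplasm of bladder, unspecified"},
  {"code": "C71.9", "name": "malignant neoplasm of brain, unspecified"},
  {"code": "C73", "name": "malignant neoplasm of thyroid gland"},
  {"code": "C81.9", "name": "Hodgkin lymphoma, unspecified"},
  {"code": "C83.3", "name": "diffuse large B-cell lymphoma"},
  {"code": "C90.0", "name": "multiple myeloma"},
  {"code": "C91.0", "name": "acute lymphoblastic leukaemia"},
  {"code": "C92.0", "name": "acute myeloblastic leukemia"},
  {"code": "C92.1", "name": "chronic myeloid leukaemia"},
  {"code": "D64.9", "name": "anaemia, unspecified"},
  {"code": "E10.9", "name": "type 1 diabetes mellitus without complications"},
  {"code": "E11.9", "name": "type 2 diabetes mellitus without complications"},
  {"code": "E66.9", "name": "obesity, unspecified"},
  {"code": "E78.5", "name": "hyperlipidaemia, unspecified"},
  {"code": "F32.9", "name": "major depressive disorder, single episode, unspecified"},
  {"code": "G20", "name": "Parkinson disease"},
  {"code": "G30.9", "name": "Alzheimer disease, unspecified"},
  {"code": "G35", "name": "multiple sclerosis"},
  {"code": "I10", "name": "essential (primary) hypertension"},
  {"code": "I21.9", "name": "acute myocardial infarction, unspecified"},
  {"code": "I25.1", "name": "atherosclerotic heart disease"},
  {"code": "I48.9", "name": "atrial fibrillation and atrial flutter, unspecified"},
  {"code": "I50.9", "name": "heart failure, unspecified"},
  {"code": "J18.9", "name": "pneumonia, unspecified organism"},
  {"code": "J44.9", "name": "chronic obstructive pulmonary disease, unspecified"},
  {"code": "J45.9", "name": "asthma, unspecified"},
  {"code": "K21.9", "name": "gastro-oesophageal reflux disease without oesophagitis"},
  {"code": "K50.9", "name": "Crohn disease, unspecified"},
  {"code": "K70.3", "name": "alcoholic cirrhosis of liver"},
  {"code": "K74.6", "name": "other and unspecified cirrhosis of liver"},
  {"code": "M05.9", "name": "seropositive rheumatoid arthritis, unspecified"},
  {"code": "N18.3", "name": "chronic kidney disease, stage 3"},
  {"code": "N18.6", "name": "end stage renal disease"},
  {"code": "Q90.9", "name": "Down syndrome, unspecified"},
  {"code": "R53", "name": "malaise and fatigue"},
  {"code": "Z00.0", "name": "general medical examination"}
]
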