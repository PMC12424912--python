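study,subject_id,type,condition,sex,age_group
COPDStudy,1001,Case,J44.9,Male,A40_49
COPDStudy,1002,Control,NA,Female,A50_59
TCGA_LIHC,3,Case,C22.0,Male,A40_49
AsthmaTrial,15,Case,J45.9,Female,A10_19
CKD_Registry,220,Case,N18.3,Other,A60_69
HF_Cohort,87,Case,I50.9,Male,A70_79
NeuroBank,901,Control,NA,Female,A30_39
OncoPanel,5520,Case,C50.9,Female,A50_59
COPDStudy,1003,Relative,NA,Unknown,A20_29
NeuroBank,902,Case,G30.9,Male,A80_89
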