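project,species,subject_id,tissue,sample_type,assay,condition,timepoint,duration,batch,replicate
CNAG_Test,Human,1,Liver,Tumor,RNA_seq,C22.0,Treatment,P1W,1,5
TARGET_AML,Human,2,Bone_marrow,Primary,Not_available,C92.0,Collection,P0N,,
GTEx,Human,17,Lung,Normal,RNA_seq,NA,Collection,P0N,,
HCA,Human,204,Blood,Normal,ATAC_seq,NA,Baseline,P1D,2,
ENCODE,Mouse,35,Brain,Cell_line,WGS,NA,Collection,P0N,,1
PCAWG,Human,998,Kidney,Tumor,WGS,C64.9,Treatment,P2W,3,2
CNAG_Test,Macaque,44,Heart,Normal,Proteomics,I50.9,Followup,P1M,,
TCGA-AML,Human,12001,Bone_marrow,Primary,RNA_seq,C92.0,Relapse,P6M,10,4
GTEx,Zebrafish,7,Colon,Normal,Methylation,NA,Baseline,P1Y,,
TARGET_AML,Human,310,Blood,Metastasis,RNA_seq,C92.1,Followup,P1M,1,1
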