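# Example codebook: controlled vocabularies for biosample and subject identifiers.
# Every term maps to a long-form `code` (human format, hyphen-free) and a compact
# `stub_code` (fixed width per component, except project/study which are
# variable-length).  `label` and `id` (ontology CURIE) are reference-only;
# `tax_code` is a reference-only 3-letter taxonomic code for species.
biosample:
  project:
    CNAG_Test:
      code: CNAG_Test
      stub_code: CT
      label: "CNAG test project"
    TARGET_AML:
      code: TARGET_AML
      stub_code: TAML
      label: "TARGET Acute Myeloid Leukemia"
      id: "NCIT:C17998"
    "TCGA-AML":
      code: TCGA_AML
      stub_code: AML
      label: "TCGA Acute Myeloid Leukemia"
      id: "NCIT:C17998"
    GTEx:
      code: GTEX
      stub_code: G
      label: "Genotype-Tissue Expression"
    GTEx_v8:
      code: GTEX_V8
      stub_code: GT
      label: "Genotype-Tissue Expression release 8"
    HCA:
      code: HCA
      stub_code: H
      label: "Human Cell Atlas"
    ENCODE:
      code: ENCODE
      stub_code: ENC
      label: "Encyclopedia of DNA Elements"
    PCAWG:
      code: PCAWG
      stub_code: PCWG
      label: "Pan-Cancer Analysis of Whole Genomes"
  species:
    Human:
      code: HomSap
      stub_code: "01"
      label: "Homo sapiens"
      id: "NCBITaxon:9606"
      tax_code: MPH
    Mouse:
      code: MusMus
      stub_code: "02"
      label: "Mus musculus"
      id: "NCBITaxon:10090"
    Macaque:
      code: MacMul
      stub_code: "03"
      label: "Macaca mulatta"
      id: "NCBITaxon:9544"
    Zebrafish:
      code: DanRer
      stub_code: "04"
      label: "Danio rerio"
      id: "NCBITaxon:7955"
  tissue:
    Liver:
      code: LIV
      stub_code: L
      label: "Liver"
      id: "UBERON:0002107"
    Bone_marrow:
      code: BMR
      stub_code: R
      label: "Bone marrow"
      id: "UBERON:0002371"
    Lung:
      code: LUN
      stub_code: U
      label: "Lung"
      id: "UBERON:0002048"
    Brain:
      code: BRN
      stub_code: N
      label: "Brain"
      id: "UBERON:0000955"
    Kidney:
      code: KID
      stub_code: K
      label: "Kidney"
      id: "UBERON:0002113"
    Heart:
      code: HRT
      stub_code: H
      label: "Heart"
      id: "UBERON:0000948"
    Blood:
      code: BLD
      stub_code: D
      label: "Blood"
      id: "UBERON:0000178"
    Colon:
      code: CLN
      stub_code: O
      label: "Colon"
      id: "UBERON:0001155"
  sample_type:
    Tumor:
      code: TUM
      stub_code: T
      label: "Tumor tissue"
      id: "NCIT:C18009"
    Primary:
      code: PRI
      stub_code: P
      label: "Primary tumor site"
    Normal:
      code: NOR
      stub_code: N
      label: "Normal tissue"
    Metastasis:
      code: MET
      stub_code: S
      label: "Metastatic tissue"
    Cell_line:
      code: CLL
      stub_code: C
      label: "Cell line"
  assay:
    RNA_seq:
      code: RNA
      stub_code: R
      label: "RNA-seq"
      id: "EFO:0008896"
    Not_available:
      code: NAV
      stub_code: n
      label: "Assay not available"
    WGS:
      code: WGS
      stub_code: W
      label: "Whole genome sequencing"
      id: "EFO:0003744"
    ATAC_seq:
      code: ATA
      stub_code: A
      label: "ATAC-seq"
      id: "EFO:0007045"
    Proteomics:
      code: PRT
      stub_code: P
      label: "Mass-spectrometry proteomics"
    Methylation:
      code: MTH
      stub_code: M
      label: "Methylation array"
  timepoint:
    Collection:
      code: COL
      stub_code: C
      label: "Sample collection"
    Treatment:
      code: TRT
      stub_code: T
      label: "Treatment event"
    Baseline:
      code: BSL
      stub_code: B
      label: "Study baseline"
    Followup:
      code: FUP
      stub_code: F
      label: "Follow-up visit"
    Relapse:
      code: RLP
      stub_code: L
      label: "Disease relapse"
subject:
  type:
    Case:
      code: Case
      stub_code: C
      label: "Case subject"
      id: "NCIT:C49152"
    Control:
      code: Control
      stub_code: O
      label: "Control subject"
    Relative:
      code: Relative
      stub_code: R
      label: "Relative of a case"
    Proband:
      code: Proband
      stub_code: P
      label: "Proband"
    Unknown:
      code: Unknown
      stub_code: U
      label: "Unknown subject type"
  sex:
    Male:
      code: Male
      stub_code: M
      label: "Male"
      id: "NCIT:C20197"
    Female:
      code: Female
      stub_code: F
      label: "Female"
      id: "NCIT:C16576"
    Other:
      code: Other
      stub_code: O
      label: "Other sex"
    Unknown:
      code: Unknown
      stub_code: U
      label: "Unknown sex"
  age_group:
    A0_9:
      code: A0_9
      stub_code: A0
      label: "Aged 0-9"
    A10_19:
      code: A10_19
      stub_code: A1
      label: "Aged 10-19"
    A20_29:
      code: A20_29
      stub_code: A2
      label: "Aged 20-29"
    A30_39:
      code: A30_39
      stub_code: A3
      label: "Aged 30-39"
    A40_49:
      code: A40_49
      stub_code: A4
      label: "Aged 40-49"
    A50_59:
      code: A50_59
      stub_code: A5
      label: "Aged 50-59"
    A60_69:
      code: A60_69
      stub_code: A6
      label: "Aged 60-69"
    A70_79:
      code: A70_79
      stub_code: A7
      label: "Aged 70-79"
    A80_89:
      code: A80_89
      stub_code: A8
      label: "Aged 80-89"
    A90_99:
      code: A90_99
      stub_code: A9
      label: "Aged 90-99"
# Rule-based components are defined by regular expressions rather than
# enumerated vocabularies.
rules:
  condition: '^(?:[A-Z][0-9]{2}(?:\.[0-9]{1,2})?|NA)$'
  duration: '^P(?:[0-9][DWMY]|0N)$'
  subject_id: '^[0-9]{1,5}$'
  batch: '^[0-9]{1,2}$'
  replicate: '^[0-9]{1,2}$'
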