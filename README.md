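# clarid

Structured, self-documenting identifiers for research subjects and
biosamples.

Most biomedical studies track subjects and specimens with opaque accessions
or UUIDs; the metadata that gives a sample meaning (tissue, diagnosis,
assay, timepoint) lives in separate tables, so even answering "what is
sample X?" means a join. `clarid` embeds that context directly in the
identifier, driven by a user-extensible YAML **codebook** of controlled
vocabularies, in two interchangeable formats:

* **human** — verbose and hyphen-delimited. A biosample identifier carries
  nine mandatory fields plus two optional ones,

  ```
  <project>-<species>-<subject_id>-<tissue>-<sample_type>-<assay>-<condition>-<timepoint>-<duration>[-B<batch>][-R<replicate>]
  ```

  and a subject identifier six:
  `<study>-<subject_id>-<type>-<condition>-<sex>-<age_group>`.
  Conditions are ICD-10 codes; durations use a restricted ISO 8601 grammar
  (`P1W` = one week, `P0N` = not available, at most 3 characters).

* **stub** — compact and delimiter-free, for filenames, labels and QR codes.
  Each vocabulary token shrinks to a fixed-width `stub_code`, the subject id
  becomes 3 Base62 characters (alphabet `0-9A-Za-z`), and the condition
  becomes a 5-character token built from its rank in a bundled, ordered
  ICD-10 lookup table. Fixed widths make the format parseable without
  delimiters.

Encoding, decoding (including ICD-10 name translation), codebook validation
against a JSON Schema, batch CSV/TSV processing with external column
mappings, and QR generation/read-back are all available as a library and as
the `clarid` command-line tool.

## Worked example

```python
from clarid import (BiosampleRecord, SubjectRecord, load_codebook, load_icd10,
                    encode_biosample, encode_subject, decode_human)

cb, icd10 = load_codebook(), load_icd10()

sample = BiosampleRecord(project="CNAG_Test", species="Human", subject_id=1,
                         tissue="Liver", sample_type="Tumor", assay="RNA_seq",
                         condition="C22.0", timepoint="Treatment",
                         duration="P1W", batch=1, replicate=5)
print(encode_biosample(sample, cb, icd10, "human"))
print(encode_biosample(sample, cb, icd10, "stub"))

subject = SubjectRecord(study="COPDStudy", subject_id=1001, type="Case",
                        condition="J44.9", sex="Male", age_group="A40_49")
print(encode_subject(subject, cb, icd10, "human"))

decoded = decode_human("TARGET_AML-HomSap-00002-BMR-PRI-NAV-C92.0-COL-P0N",
                       "biosample", cb, icd10, with_condition_name=True)
print(decoded.record.tissue, "|", decoded.condition_name)
```

prints

```
CNAG_Test-HomSap-00001-LIV-TUM-RNA-C22.0-TRT-P1W-B01-R05
CT01001LTR00701T1WB01R05
COPDStudy-01001-Case-J44.9-Male-A40_49
Bone_marrow | acute myeloblastic leukemia
```

The first line reads: CNAG test project, *Homo sapiens*, subject 1, liver,
tumor tissue, RNA-seq, ICD-10 C22.0 (liver cell carcinoma), sampled one week
after treatment, batch 1, replicate 5. The second line is the same record as
a 24-character stub: `CT` (project) + `01` (species) + `001` (Base62 subject
id) + `L`/`T`/`R` (tissue/sample type/assay) + `00701` (condition rank
token) + `T` (timepoint) + `1W` + `B01R05`.

The same works from the shell:

```bash
clarid code --action encode --entity subject \
    --set study=COPDStudy --set subject_id=1001 --set type=Case \
    --set condition=J44.9 --set sex=Male --set age_group=A40_49
clarid code --action encode --format stub --entity biosample \
    -i samples.csv -o samples_with_ids.csv --mapping mapping.yaml
clarid validate --codebook my_codebook.yaml
clarid qrcode --generate CT01001LTR00701T1WB01R05 -o sample.png
clarid qrcode --read sample.png
```

Batch inputs with arbitrary column names are adapted through a YAML mapping
config (column renames, value recodes, `NA` standardization, decade age
binning, and UUID→numeric subject-id conversion by order of first
appearance).

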