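"""Fixed-width layout constants shared by the encoder, decoder and codebook checks.

The stub format is delimiter-free, so parsing is only decidable because every
component (except the leading project/study token and the trailing duration
payload) has a fixed width.  These widths are the single source of truth.
"""

# Base62 positional alphabet: digits, then upper case, then lower case.
BASE62_ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
BASE62_INDEX = {c: i for i, c in enumerate(BASE62_ALPHABET)}

# Width of the zero-padded decimal subject id in human format.
SUBJECT_ID_HUMAN_WIDTH = 5
SUBJECT_ID_MAX = 99999

# Base62 width of the subject id in stub format (62**3 - 1 = 238327 >= 99999).
SUBJECT_ID_STUB_WIDTH = 3

# Condition stub: 3-char Base62 rank in the ICD-10 table + a reserved "01" suffix.
CONDITION_RANK_WIDTH = 3
CONDITION_STUB_SUFFIX = "01"
CONDITION_STUB_WIDTH = CONDITION_RANK_WIDTH + len(CONDITION_STUB_SUFFIX)

# Fixed stub widths per vocabulary component.  Project and study stub codes are
# variable-length (free-text fields compressed via a user-defined stub_code).
STUB_WIDTHS = {
    "biosample": {
        "species": 2,
        "tissue": 1,
        "sample_type": 1,
        "assay": 1,
        "timepoint": 1,
    },
    "subject": {
        "type": 1,
        "sex": 1,
        "age_group": 2,
    },
}

# Order of the fixed-width stub slices after the project prefix (biosample) or
# before computing the study prefix (subject).  Durations are the variable tail
# of the biosample core.
BIOSAMPLE_STUB_SLICES = (
    ("species", 2),
    ("subject_id", SUBJECT_ID_STUB_WIDTH),
    ("tissue", 1),
    ("sample_type", 1),
    ("assay", 1),
    ("condition", CONDITION_STUB_WIDTH),
    ("timepoint", 1),
)

SUBJECT_STUB_SLICES = (
    ("subject_id", SUBJECT_ID_STUB_WIDTH),
    ("type", 1),
    ("condition", CONDITION_STUB_WIDTH),
    ("sex", 1),
    ("age_group", 2),
)

# Total width of the fixed subject tail (everything after the study prefix).
SUBJECT_STUB_TAIL = sum(w for _, w in SUBJECT_STUB_SLICES)  # 12

# Fixed part of the biosample core after the project prefix, excluding the
# 1-2 character duration payload.
BIOSAMPLE_STUB_FIXED = sum(w for _, w in BIOSAMPLE_STUB_SLICES)  # 14

# Optional suffix tokens appended to both formats.
BATCH_PREFIX = "B"
REPLICATE_PREFIX = "R"
OPTIONAL_DIGITS = 2

# Human-format vocabulary codes are restricted so the hyphen stays reserved.
HUMAN_CODE_CHARS = r"[A-Za-z0-9_.]"
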