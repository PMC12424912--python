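"""Seeded record generation and reference examples.

Everything tests and demonstrations need without external downloads: a
reproducible generator of valid records drawn from the bundled codebook and
ICD-10 table, the four worked (record, human identifier) pairs, and an
adversarial corpus of non-identifier strings for decoder error-totality
checks.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass

from .codebook import Codebook, ICD10Table
from .encoder import BiosampleRecord, SubjectRecord
from .errors import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "generate_records",
    "worked_examples",
    "adversarial_inputs",
]

#: Valid durations sampled by the generator.
DURATION_POOL = ("P1D", "P1W", "P2W", "P1M", "P6M", "P1Y", "P0N")

#: Free-form study names (hyphen-free so human and stub round-trips agree).
STUDY_POOL = ("COPDStudy", "AsthmaTrial", "CKD_Registry", "HF_Cohort",
              "NeuroBank", "OncoPanel")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n: int = 100
    entity: str = "biosample"
    optional_rate: float = 0.5
    na_rate: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.optional_rate <= 1.0 or not 0.0 <= self.na_rate <= 1.0:
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.entity not in ("biosample", "subject"):
            raise ConfigurationError(f"unknown entity {self.entity!r}")


def _terms(cb: Codebook, entity: str, component: str) -> list[str]:
    terms = sorted(cb.vocabulary(entity, component))
    if not terms:
        raise ConfigurationError(f"empty vocabulary for {entity}.{component}")
    return terms


def generate_records(cfg: GeneratorConfig, cb: Codebook, table: ICD10Table):
    """Sample ``cfg.n`` valid records, reproducibly under ``cfg.seed``."""
    rng = random.Random(cfg.seed)
    conditions = [code for code, _ in table.entries if code != "NA"]
    records = []
    if cfg.entity == "biosample":
        pools = {c: _terms(cb, "biosample", c)
                 for c in ("project", "species", "tissue", "sample_type", "assay", "timepoint")}
        for _ in range(cfg.n):
            na = rng.random() < cfg.na_rate
            batch = rng.randint(1, 99) if rng.random() < cfg.optional_rate else None
            replicate = rng.randint(1, 99) if rng.random() < cfg.optional_rate else None
            records.append(BiosampleRecord(
                project=rng.choice(pools["project"]),
                species=rng.choice(pools["species"]),
                subject_id=rng.randint(1, 99999),
                tissue=rng.choice(pools["tissue"]),
                sample_type=rng.choice(pools["sample_type"]),
                assay="Not_available" if na else rng.choice(pools["assay"]),
                condition="NA" if na else rng.choice(conditions),
                timepoint=rng.choice(pools["timepoint"]),
                duration="P0N" if na else rng.choice(DURATION_POOL),
                batch=batch,
                replicate=replicate,
            ))
    else:
        pools = {c: _terms(cb, "subject", c) for c in ("type", "sex", "age_group")}
        for _ in range(cfg.n):
            na = rng.random() < cfg.na_rate
            records.append(SubjectRecord(
                study=rng.choice(STUDY_POOL),
                subject_id=rng.randint(1, 99999),
                type=rng.choice(pools["type"]),
                condition="NA" if na else rng.choice(conditions),
                sex=rng.choice(pools["sex"]),
                age_group=rng.choice(pools["age_group"]),
            ))
    return records


def worked_examples():
    """The four reference (record, expected human identifier) pairs."""
    return [
        (
            BiosampleRecord(project="CNAG_Test", species="Human", subject_id=1,
                            tissue="Liver", sample_type="Tumor", assay="RNA_seq",
                            condition="C22.0", timepoint="Treatment", duration="P1W",
                            batch=1, replicate=5),
            "CNAG_Test-HomSap-00001-LIV-TUM-RNA-C22.0-TRT-P1W-B01-R05",
        ),
        (
            SubjectRecord(study="COPDStudy", subject_id=1001, type="Case",
                          condition="J44.9", sex="Male", age_group="A40_49"),
            "COPDStudy-01001-Case-J44.9-Male-A40_49",
        ),
        (
            BiosampleRecord(project="TARGET_AML", species="Human", subject_id=2,
                            tissue="Bone_marrow", sample_type="Primary",
                            assay="Not_available", condition="C92.0",
                            timepoint="Collection", duration="P0N"),
            "TARGET_AML-HomSap-00002-BMR-PRI-NAV-C92.0-COL-P0N",
        ),
        (
            SubjectRecord(study="TCGA-LIHC", subject_id=3, type="Case",
                          condition="C22.0", sex="Male", age_group="A40_49"),
            "TCGA_LIHC-00003-Case-C22.0-Male-A40_49",
        ),
    ]


def adversarial_inputs(seed: int, n: int, valid_identifiers=()) -> list[str]:
    """Fuzz corpus: random ASCII strings plus one-character edits of valid ids."""
    rng = random.Random(seed)
    alphabet = string.printable[:94]  # printable ASCII without whitespace controls
    corpus = ["", "-", "A"]
    while len(corpus) < n:
        if valid_identifiers and rng.random() < 0.4:
            base = rng.choice(list(valid_identifiers))
            kind = rng.randrange(3)
            pos = rng.randrange(len(base))
            if kind == 0:  # delete
                corpus.append(base[:pos] + base[pos + 1:])
            elif kind == 1:  # substitute
                corpus.append(base[:pos] + rng.choice(alphabet) + base[pos + 1:])
            else:  # insert
                corpus.append(base[:pos] + rng.choice(alphabet) + base[pos:])
        else:
            corpus.append("".join(rng.choice(alphabet)
                                  for _ in range(rng.randrange(65))))
    return corpus[:n]
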