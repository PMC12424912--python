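"""Codebook loading, validation and lookup behavior."""

import json

import pytest

from clarid.codebook import (
    ICD10Table,
    bundled_codebook_path,
    condition_rank,
    load_codebook,
    load_icd10,
    rank_to_condition,
    resolve_term,
    reverse_lookup,
    validate_codebook,
)
from clarid.errors import (
    CodebookError,
    ConditionLookupError,
    ConfigurationError,
    VocabularyError,
)


class TestLoad:
    def test_bundled_species_entry(self, cb):
        human = resolve_term(cb, "biosample", "species", "Human")
        assert human.code == "HomSap"
        assert human.stub_code == "01"
        assert human.id == "NCBITaxon:9606"
        assert human.tax_code == "MPH"

    def test_empty_document_rejected(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("", encoding="utf-8")
        with pytest.raises(CodebookError, match="missing entity sections"):
            load_codebook(path)

    def test_duplicate_stub_code_names_component(self, mutate, write_codebook):
        doc = mutate(lambda d: d["biosample"]["tissue"]["Lung"].update(stub_code="L"))
        with pytest.raises(CodebookError, match=r"biosample\.tissue.*duplicate stub_code 'L'"):
            load_codebook(write_codebook(doc))

    def test_unknown_entry_key_is_warning_not_error(self, mutate, write_codebook):
        doc = mutate(lambda d: d["biosample"]["tissue"]["Liver"].update(color="red"))
        cb = load_codebook(write_codebook(doc))
        assert any("color" in w.path for w in cb.warnings)

    def test_yaml_syntax_error(self, tmp_path):
        path = tmp_path / "broken.yaml"
        path.write_text("a: [unclosed", encoding="utf-8")
        with pytest.raises(CodebookError, match="YAML syntax error"):
            load_codebook(path)


class TestValidate:
    def test_bundled_codebook_passes_shipped_schema(self):
        report = validate_codebook(bundled_codebook_path())
        assert report.valid
        assert report.errors() == []

    def test_missing_stub_code_single_finding(self, mutate, write_codebook):
        doc = mutate(lambda d: d["biosample"]["assay"]["WGS"].pop("stub_code"))
        report = validate_codebook(write_codebook(doc))
        assert not report.valid
        errors = report.errors()
        assert len(errors) >= 1
        assert all("WGS" in f.path for f in errors)
        assert any("stub_code" in f.message for f in errors)

    def test_malformed_schema_is_configuration_error(self, tmp_path):
        schema = tmp_path / "schema.json"
        schema.write_text("{not json", encoding="utf-8")
        with pytest.raises(ConfigurationError):
            validate_codebook(bundled_codebook_path(), schema)

    def test_idempotent(self, mutate, write_codebook):
        doc = mutate(lambda d: d["biosample"]["tissue"]["Liver"].update(code="LI-V"))
        path = write_codebook(doc)
        r1 = validate_codebook(path)
        r2 = validate_codebook(path)
        assert r1.findings == r2.findings
        assert not r1.valid

    @pytest.mark.parametrize("mutation, needle", [
        (lambda d: d["biosample"]["assay"]["WGS"].pop("stub_code"), "stub_code"),
        (lambda d: d["biosample"]["tissue"]["Lung"].update(stub_code="L"), "duplicate stub_code"),
        (lambda d: d["biosample"]["tissue"]["Lung"].update(code="LIV"), "duplicate code"),
        (lambda d: d["subject"]["sex"]["Male"].update(code="Ma-le"), "hyphen"),
        (lambda d: d["biosample"]["species"]["Human"].update(stub_code="001"), "width"),
    ], ids=["missing-stub", "dup-stub", "dup-code", "hyphen-code", "wrong-width"])
    def test_mutation_classes_each_yield_an_error(self, mutate, write_codebook,
                                                  mutation, needle):
        report = validate_codebook(write_codebook(mutate(mutation)))
        assert not report.valid
        assert any(needle in f.message for f in report.errors())


class TestLookup:
    def test_forward_lookup_examples(self, cb):
        liver = resolve_term(cb, "biosample", "tissue", "Liver")
        assert (liver.code, liver.id) == ("LIV", "UBERON:0002107")
        rna = resolve_term(cb, "biosample", "assay", "RNA_seq")
        assert (rna.code, rna.stub_code) == ("RNA", "R")

    def test_lookup_is_case_sensitive(self, cb):
        with pytest.raises(VocabularyError, match="valid terms"):
            resolve_term(cb, "biosample", "tissue", "liver")

    def test_reverse_lookup_both_formats(self, cb):
        assert reverse_lookup(cb, "biosample", "tissue", "LIV", "human") == "Liver"
        assert reverse_lookup(cb, "biosample", "tissue", "L", "stub") == "Liver"

    def test_reverse_lookup_unknown_token(self, cb):
        with pytest.raises(VocabularyError):
            reverse_lookup(cb, "subject", "sex", "X", "stub")

    def test_code_and_stub_maps_are_bijective(self, cb):
        for entity, components in cb.entities.items():
            for component, terms in components.items():
                for term, entry in terms.items():
                    assert reverse_lookup(cb, entity, component, entry.code, "human") == term
                    if entry.stub_code is not None:
                        assert reverse_lookup(cb, entity, component, entry.stub_code, "stub") == term


class TestICD10:
    def test_na_sentinel_is_rank_zero(self, icd10):
        assert condition_rank(icd10, "NA") == 0

    def test_rank_roundtrip_named_example(self, icd10):
        code, name = rank_to_condition(icd10, condition_rank(icd10, "C22.0"))
        assert (code, name) == ("C22.0", "liver cell carcinoma")

    def test_rank_bijective_over_whole_table(self, icd10):
        for rank in range(len(icd10)):
            code, _ = rank_to_condition(icd10, rank)
            assert condition_rank(icd10, code) == rank

    def test_unknown_code_and_rank(self, icd10):
        with pytest.raises(ConditionLookupError):
            condition_rank(icd10, "Z99.99")
        with pytest.raises(ConditionLookupError):
            rank_to_condition(icd10, len(icd10))

    def test_unsorted_table_rejected(self):
        with pytest.raises(CodebookError, match="sorted"):
            ICD10Table([("NA", "not available"), ("J44.9", "x"), ("C22.0", "y")])

    def test_table_without_sentinel_rejected(self, tmp_path):
        path = tmp_path / "t.json"
        path.write_text(json.dumps([{"code": "C22.0", "name": "x"}]), encoding="utf-8")
        with pytest.raises(CodebookError, match="NA"):
            load_icd10(path)


def test_printed_vocabulary_tokens_all_resolve(cb):
    """Every code and stub token from the reference examples is in the codebook."""
    human_tokens = [("biosample", "species", "HomSap"), ("biosample", "tissue", "LIV"),
                    ("biosample", "sample_type", "TUM"), ("biosample", "assay", "RNA"),
                    ("biosample", "timepoint", "TRT"), ("biosample", "tissue", "BMR"),
                    ("biosample", "sample_type", "PRI"), ("biosample", "assay", "NAV"),
                    ("biosample", "timepoint", "COL"), ("subject", "type", "Case"),
                    ("subject", "sex", "Male"), ("subject", "age_group", "A40_49")]
    for entity, component, token in human_tokens:
        assert reverse_lookup(cb, entity, component, token, "human")
    stub_tokens = [("biosample", "species", "01"), ("biosample", "tissue", "L"),
                   ("biosample", "sample_type", "T"), ("biosample", "assay", "R"),
                   ("biosample", "assay", "n"), ("subject", "type", "C"),
                   ("subject", "sex", "M"), ("subject", "age_group", "A4")]
    for entity, component, token in stub_tokens:
        assert reverse_lookup(cb, entity, component, token, "stub")
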