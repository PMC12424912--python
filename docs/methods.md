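# Methods

## The identifier model

An identifier is an ordered sequence of components, each drawn from a
controlled vocabulary or matched by a regular expression. The codebook is
the single source of truth: per entity (`biosample`, `subject`) and
component it maps each term to a long-form `code` (human format) and a
compact `stub_code` (stub format), plus reference-only `label`, ontology
CURIE `id` (e.g. `UBERON:0002107`) and, for species, a `tax_code`.
Rule-based components — `condition`, `subject_id`, `duration`, `batch`,
`replicate` — are defined by regexes in the codebook's `rules` section;
defaults are built in and individual rules may be overridden.

Human format joins component codes with hyphens; the hyphen is therefore
reserved, codes are restricted to `[A-Za-z0-9_.]`, and free-form study names
have hyphens replaced by underscores on encoding. Subject decoding is
right-anchored (the last five tokens are fixed; the rest is the study),
biosample decoding left-anchored with trailing `B##`/`R##` optionals
recognized by shape.

Stub format concatenates fixed-width tokens:

| element | width | content |
|---|---|---|
| project / study | variable | `stub_code` (project) or verbatim study |
| species | 2 | `stub_code` |
| subject_id | 3 | Base62, alphabet `0-9A-Z a-z` |
| tissue, sample_type, assay, timepoint / type, sex | 1 | `stub_code` |
| condition | 5 | Base62 rank in ICD-10 table (3) + reserved `01` |
| age_group | 2 | `A` + decade digit |
| duration | 1–2 | duration minus the leading `P` |
| batch / replicate | 3 each | `B`/`R` + 2 digits |

A biosample stub is `|project stub| + 14 + |duration payload| + 3·k`
characters (k optionals); a subject stub is `|study| + 12`. The worked
records produce 24- and 21-character stubs.

Because only the leading project/study token and the trailing duration
payload vary in length, delimiter-free parsing is decidable: the project is
recovered by trying every project stub code that prefixes the identifier
and keeping the unique one whose remainder parses completely. Under the
default grammar ambiguity is impossible — two distinct project stubs can
only both prefix an identifier if their lengths differ, a difference of one
forces duration payloads of 2 vs 1 characters, and the fixed `01` condition
suffix then requires one character to be both `1` and `0` — but the
ambiguity error path exists and is reported distinctly from "no match",
since user codebooks may loosen the duration rule.

## Conditions

Clinical conditions are ICD-10 codes validated against a bundled JSON
lookup table: the `NA` sentinel at rank 0 followed by codes sorted
lexicographically. The table bundled here is a 52-code excerpt spanning
common oncology, respiratory, cardiovascular, metabolic and neurological
diagnoses; it is user-replaceable, and because the stub condition token
encodes the *rank* in the table, stub identifiers are only comparable
across datasets that share a table. The 2-character suffix of the condition
token is reserved and fixed at `01`. The `--with-condition-name` decode
option translates codes back to display names from the same table.

## Durations

Durations follow a restricted ISO 8601 grammar: `P` + one digit + a unit in
`{D, W, M, Y}`, or the sentinel `P0N` ("not available"), never more than 3
characters. Within the 3-character bound the digit count is exactly one, so
the stub's duration payload is 2 characters under the default rule; the
parser tolerates 1-character payloads so that codebooks overriding
`rules.duration` (e.g. admitting `PW`) still round-trip.

## Missing values

Inputs standardized as `NA` (configurable `na_values`) map to: condition
`NA` (rank 0), duration `P0N`, assay `Not_available`; batch and replicate
are simply omitted. A missing value in any other required component is a
row error — identifiers with too many unknowns stop being informative, so
the tool refuses to fabricate them.

## Batch processing and mapping configs

CSV/TSV files (dialect by extension, UTF-8, header row) are processed row
by row; failures are collected per row — with the row number, error class
and message — rather than aborting, and `--strict` restores fail-fast. A
YAML mapping config adapts arbitrary input schemas: `column_map` renames
columns to components, `value_recodes` fixes vocabulary mismatches
(`male` → `Male`), `age_bins` bins a raw age column into decade terms
`A0_9` … `A90_99` (inclusive bounds, `floor(age)` binned, bins must be
non-overlapping and cover 0–99), and `id_strategy: uuid_order` converts
UUIDs to numeric subject ids by 1-based rank of first appearance in the
file, so repeated UUIDs share an id. Subject ids are bounded at 99,999 by
the 5-digit zero-padded human token (the 3-character Base62 stub token
would allow 238,327).

## Codebook validation

`validate` checks a codebook YAML against a JSON Schema (draft 2020-12; a
schema document that is itself malformed is a configuration error, not a
finding) and then applies layout-specific rules the schema cannot express:
per-component uniqueness of terms, codes and stub codes; stub widths
matching the table above; no hyphens in codes; CURIE-shaped `id` values.
Unknown keys and unknown components are warnings, not errors — the
codebook is explicitly user-extensible. Duplicate stub codes *across*
components are legal because stub parsing is positional.

The schema validator is a small built-in draft-2020-12 subset
(`type`, `properties`, `patternProperties`, `additionalProperties`,
`required`, `pattern`, length/count bounds, `enum`, `items`, local `$ref`);
unsupported annotation keywords are ignored, as full validators do.

## QR codes

`clarid/qr.py` is a self-contained Model-2 QR codec: byte mode, error
correction level L, versions 1–5 (payloads to 106 characters), mask 0,
Reed–Solomon parity over GF(256) with polynomial 0x11D. PNGs are rendered
at 8 px/module with a 4-module quiet zone. The reader targets the images
this module writes: it grid-samples an upright, high-contrast symbol,
recovers mask and EC level from the format information (nearest of the 32
valid BCH codes), and verifies the Reed–Solomon syndromes exactly instead
of attempting correction — a corrupted symbol is reported as unreadable.
It is not a general-purpose scanner: rotation, perspective and print noise
are out of scope.

## Synthetic records

The seeded generator samples uniformly from the bundled codebook
vocabularies and ICD-10 table: subject ids 1–99,999, durations from
`{P1D, P1W, P2W, P1M, P6M, P1Y, P0N}`, batch/replicate present with
probability `optional_rate` (default 0.5), and a "missing data" mode with
probability `na_rate` (default 0.1) that sets condition `NA`, duration
`P0N` and assay `Not_available` together, mimicking records whose clinical
annotation is absent. Study names are drawn from a hyphen-free pool, so
round trips are exact in both formats (a hyphenated study is, by design,
sanitized in human format; stub format keeps it verbatim). What the
generator does not emulate: correlated metadata (tissue–diagnosis
consistency), real-world vocabulary drift, non-UTF-8 files, or codebooks
other than the bundled one — passing round trips show the codec is
self-consistent at scale, not that any particular external dataset maps
cleanly onto the bundled vocabularies.

Problem sizes used by the test suite and the acceptance script: 1,000
records per entity for round trips (4,000 encode/decode pairs), the full
238,328-value Base62 sweep, 100 identifiers per entity and format for QR
round trips, and a 10,000-row synthetic subject table for the batch check —
a deliberately desk-scale analogue of bulk repository conversion.

## Design choices and limitations

* The Base62 alphabet is digits, then upper case, then lower case; subject
  1001 encodes to `0G9`.
* One condition per identifier; multi-morbidity belongs in full metadata
  systems.
* Technical provenance (plates, vials, centers, lots) is deliberately not
  encodable; such detail belongs in a LIMS keyed by a primary identifier.
* Identifiers are not primary keys: two biosamples from the same subject
  under identical conditions share an identifier unless batch/replicate
  distinguish them, and a metadata change implies re-encoding.
* Decoding is strict — no case folding or internal whitespace tolerance;
  only leading/trailing whitespace of the whole string is trimmed.
* Free-text projects must define a `stub_code` before stub encoding is
  possible; requesting one without it is a configuration error.
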