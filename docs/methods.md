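# Methods

## Model

`exosift` implements a fixed-order filter cascade over annotated exome
variant tables. Each of steps 1–6 is a pure per-record predicate, so the
final survivor set is the conjunction of all keep-predicates; only the
intermediate attrition counts depend on the order. Step 7 (disease
linking) is an annotation-and-ranking pass, not a model: matching is
lexical keyword matching against local gene–disorder tables.

The intended inputs are wANNOVAR/ANNOVAR "multianno"-style TSVs. Column
headers drifted across annotation releases, so columns resolve through a
case-insensitive alias table (`table_io.WANNOVAR_ALIASES`); generic TSVs
work through a user-supplied role→header map in YAML. Coordinates are
1-based end-inclusive (ANNOVAR convention) and are never remapped.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `exonic_keep` | `{exonic, exonic;splicing}` | region classes kept at step 1 |
| `include_splicing` | off | adds `splicing` to the keep-set |
| `exonic_func_remove` | synonymous SNV + 3 nonframeshift classes | classes removed at step 2 |
| `freq_threshold_1kgp` / `freq_threshold_esp` | 0.01 | rarity cutoff as a fraction; remove when frequency **> threshold** |
| `gerp_min` | 0.0 | keep when GERP **≥** bound (removes exactly the negatives) |
| `fathmm_max` | 1.0 | keep when FATHMM **≤** bound; `strict` preset: −1.5 |
| `keep_missing_freq` / `_gerp` / `_fathmm` | on | keep records lacking the value |

Boundary semantics follow the published rule texts exactly: a frequency of
1 % or less is rare (kept); GERP 0 is not negative (kept); FATHMM exactly
at the cutoff is kept (removal is strictly greater-than). All boundaries
are configurable, never hard-coded into the predicates.

The two FATHMM cutoffs both appear in the source tool's description — 1.0
as the value its own stepwise results used, −1.5 as the conventional
FATHMM damaging threshold it recommends for broad use. We resolve the
conflict by defaulting to 1.0 (the value the published counts were
actually produced with) and exposing −1.5 as the `strict` preset; the
presets differ in `fathmm_max` only, which the acceptance suite asserts.

Step 2's removal set is read as *nonframeshift indel classes plus
synonymous SNVs* — not "everything that is not a frameshift". The literal
reading would delete nonsynonymous SNVs, contradicting the fact that the
framework's own validation hits (all missense) survive it.

Missing scores are kept at every step. The source framework states this
rule only for frequencies ("no available frequency data are prioritized");
we generalize it to GERP and FATHMM because frameshift indels surviving
step 2 typically carry neither score, yet appear in downstream survivor
counts. Each `keep_missing_*` flag can be disabled independently, and the
suite checks the monotonicity law: disabling a keep-missing flag never
increases the survivor count.

Step 7 ambiguity: the framework's prose reads like prioritization, its
stepwise result table shows a small removal. Both modes exist; the default
is annotate+rank (hypothesis-free), `drop_unmatched` reproduces the
attrition and removes only genes with *no* disorder annotation at all (an
annotated-but-unmatched gene survives with score 0).

## Synthetic data

The generator builds tables from *strata*: homogeneous row blocks whose
field specs are a fixed value, a uniform range, or missing. Ranges may not
straddle a filter boundary (rejected as ambiguous), so the expected
survivor count after every step is computable from the strata definitions
alone — the "expectation ledger", computed by interval logic, never by
running the engine. Engine-equals-ledger is the core acceptance property.

The bundled `table1-mini` profile reproduces, at 1/10 scale (~5 573 rows),
the attrition shape of a real published Parkinson's-disease exome run
(55 726 → 19 727 → 9 465 → 1 281 → 917 → 718 → 262 → 252), plus one
planted causal-like variant (exonic, missense, unobserved in both
frequency panels, GERP 4.8, FATHMM −3.2, disease-matched gene) that must
survive all seven steps and rank first. Headline counts from real patient
exomes depend on private data and version-pinned databases and are not
reproducible at desk scale; the scaled profile tests the *mechanism*, not
the published numbers.

What the generator does **not** emulate: realistic allele-frequency
spectra, linkage between fields, genotypes, multi-sample columns, or
annotation noise. A green ledger test therefore establishes that the
filter logic and accounting are exact on tables of the right shape and
dialect — not that the thresholds are clinically optimal.

## Numerical and design choices

- Frequencies are validated into [0, 1] at parse time; a cell equal to the
  missing token (default `.`) or empty parses to `None` and can never
  compare equal to a number. Lenient mode converts unparsable numeric
  cells to missing with a logged count; strict mode (default) raises with
  the line number.
- Parsing is locale-independent: decimal point only, thousands separators
  rejected.
- Float formatting on output uses `repr` round-tripping (integers printed
  bare), making write→read→write byte-stable; determinism of the CLI is
  asserted byte-for-byte.
- Ranking is a stable sort descending by score; ties keep original table
  order, so step 7 never reorders equally-scored variants.
- Keyword matching is case-insensitive whole-word (`\b`-delimited regex on
  whitespace-normalized descriptions): "epilepsy" does not match
  "epileptic". Anything semantic (ontologies, phenotype similarity) is
  deliberately out of scope — the design contrast with phenotype-driven
  prioritizers is the point of a hypothesis-free tool.
- Multi-gene cells (`GENE1;GENE2`) are split for disease lookup but
  preserved verbatim in output.
- Rows are the unit of filtering; multi-allelic decomposition is
  upstream's concern.

## Oracles in the test suite

Two independent routes back every engine claim: a brute-force restatement
of the six keep rules written directly from the rule texts
(`tests/conftest.py::oracle_keep`), checked against the cascade on 1 000
seeded random tables; and the analytic stratum ledger, checked on every
fixture profile. The disease-map generator's ledger is cross-checked by a
raw regex scan over the emitted file.

## Limitations

- Consumes pre-annotated tables only; it never calls an annotation
  service and never re-annotates.
- VCF input is supported solely for record-count provenance checks.
- The gene–disease step needs user-supplied local TSVs (OMIM licensing
  forbids redistribution); shipped fixtures are synthetic.
- No inheritance-model, trio, or compound-heterozygote logic, by design.
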