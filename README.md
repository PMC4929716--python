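# exosift

Seven-level filtration and prioritization of annotated whole-exome variant
tables.

Given a tab-delimited variant table from ANNOVAR or wANNOVAR (one row per
variant, annotated with functional class, population allele frequencies,
and conservation/pathogenicity scores), `exosift` reduces tens of
thousands of calls to a shortlist of plausible disease candidates. It is
aimed at small labs doing Mendelian-disease exome studies without a
bioinformatics core: the filtering is *hypothesis-free* — no inheritance
model, no phenotype-similarity scoring — so no prior clinical detail about
the patient is required.

## The filter cascade

Steps applied in fixed order, each with attrition accounting:

1. **Exonic regions** — keep rows with `Func.refGene ∈ {exonic,
   exonic;splicing}` (optionally also `splicing`).
2. **Functional class** — remove synonymous SNVs and non-frameshift
   indels/substitutions; keep missense, stopgain/stoploss, frameshift
   indels, and unknown.
3. **1000 Genomes rarity** — remove variants with 1KGP frequency
   *f* > 0.01; *f* ≤ 0.01 is rare, and variants with no frequency entry
   are prioritized (kept).
4. **ESP6500 rarity** — the same 1 % rule against the NHLBI Exome
   Sequencing Project frequencies.
5. **Conservation** — remove variants with negative GERP score
   (GERP ≥ 0 survives; GERP > 0 indicates a conserved position).
6. **Pathogenicity** — remove variants with FATHMM score > 1.0
   (negative FATHMM predicts damaging). A `strict` preset uses the
   conventional FATHMM cutoff of −1.5; the two presets differ in nothing
   else.
7. **Disease link** — look surviving genes up in local OMIM/DISEASES-style
   gene–disorder tables and rank variants by the number of distinct
   disease keywords matched (case-insensitive whole-word matching; ties
   keep table order). By default this only annotates and ranks;
   `--drop-unmatched` removes genes with no disorder annotation at all.

Missing values (`.` cells) are a first-class state at every step and are
kept by default — frameshift indels that survive step 2 usually carry
neither a GERP nor a FATHMM score.

## Worked example

Generate a synthetic exome-shaped table (strata with known composition,
including one planted causal-like variant) and run the pipeline:

```sh
exosift simulate --profile table1-mini --seed 7 --out-dir sim/
exosift -v run --input sim/table.tsv --out-dir out/ \
    --disease-map sim/disease_map.tsv \
    --query parkinsonism --query ataxia --query microcephaly --query brain \
    --drop-unmatched
```

The run logs the stepwise attrition to stderr:

```
INFO Total number of variants in input: 5573
INFO STEP 1: variants assigned to exonic regions: 1973
INFO STEP 2: synonymous and non-frameshift variants removed: 947
INFO STEP 3: variants with 1KGP frequency > 1% removed: 129
INFO STEP 4: variants with ESP6500 frequency > 1% removed: 93
INFO STEP 5: variants with GERP score < 0 removed: 73
INFO STEP 6: variants with FATHMM score > 1 removed: 27
INFO STEP 7: variants linked to relevant diseases: 26
```

5 573 input rows shrink to a 26-variant shortlist. `out/shortlist.tsv`
ranks the planted causal-like variant (gene `SPIKE1`, unobserved in both
frequency references, GERP 4.8, FATHMM −3.2) first with `disease_score`
2 — its gene's disorder description matched two query keywords. These
counts equal, step for step, the analytic expectation ledger the
simulator wrote to `sim/ledger.json`: every filter decision on a
stratified table is predictable from the strata alone, which is what the
test suite leans on. `out/` also contains `cascade.tsv`/`cascade.json`
(the attrition report) and `manifest.json` (the fully resolved
configuration; re-running it reproduces byte-identical outputs).

The library API mirrors the CLI: `read_table`, `run_cascade`,
`match_diseases`, `rank_shortlist`, `write_shortlist`; see the module
docstrings.

## Acceptance script

`scripts/acceptance.py` regenerates the stratified synthetic exome from
scratch, runs the full seven-step pipeline through the public API,
verifies the cascade counts against the generator's independent analytic
ledger and that the planted causal-like variant survives and ranks first,
then writes its results JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
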