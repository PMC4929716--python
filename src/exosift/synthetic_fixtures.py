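"""Synthetic annotated variant tables with analytically known attrition.

Every fixture is built from *strata*: blocks of rows sharing a functional
class and per-field value specifications. A field spec is either a fixed
value, a ``(low, high)`` range sampled uniformly, or ``None`` for missing.
Because each stratum is homogeneous with respect to every filter decision
(ranges must fall entirely on one side of the relevant threshold — a
straddling range is rejected as ambiguous), the expected survivor count
after each cascade step is computable from the stratum definitions alone,
without running the filter engine. That analytic *expectation ledger* is
what the engine is tested against.

The generator emulates the table shape only: column dialect, functional
class vocabulary, frequency/score strata including missing values, and
multi-gene cells. It does not attempt realistic allele-frequency spectra,
linkage, or genotypes — survivor counts, not population genetics, are what
the fixtures make predictable.

Identical (strata, seed) inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import StratumError
from .filter_engine import FilterConfig
from .table_io import VariantRecord, write_shortlist

FieldSpec = None | float | tuple[float, float]

_BASES = ("A", "C", "G", "T")

#: Disorder phrase vocabulary for synthetic gene–disease maps.
DEFAULT_VOCABULARY = (
    "early-onset parkinsonism",
    "ataxia with myoclonic epilepsy",
    "epileptic encephalopathy",
    "severe intellectual disability",
    "microcephaly",
    "spastic paraplegia",
    "cardiomyopathy, dilated",
    "retinitis pigmentosa",
    "congenital deafness",
    "brain disorder, unspecified",
)


@dataclass(frozen=True)
class StratumSpec:
    """One homogeneous block of synthetic variant rows.

    ``freq_1kgp``, ``freq_esp6500``, ``gerp`` and ``fathmm`` accept a fixed
    value, a ``(low, high)`` uniform range, or ``None`` for missing.
    ``exonic_func=None`` emits the missing token. ``label`` names the
    stratum in the expectation ledger.
    """

    n: int
    func_region: str = "exonic"
    exonic_func: str | None = "nonsynonymous SNV"
    freq_1kgp: FieldSpec = None
    freq_esp6500: FieldSpec = None
    gerp: FieldSpec = None
    fathmm: FieldSpec = None
    gene_pool: tuple[str, ...] = ("GENE1",)
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 0:
            raise StratumError(f"stratum {self.label!r}: n must be >= 0")
        if not self.gene_pool:
            raise StratumError(f"stratum {self.label!r}: empty gene_pool")
        for name in ("freq_1kgp", "freq_esp6500", "gerp", "fathmm"):
            spec = getattr(self, name)
            if isinstance(spec, tuple):
                if len(spec) != 2 or spec[0] > spec[1]:
                    raise StratumError(
                        f"stratum {self.label!r}: malformed range for {name}: {spec!r}"
                    )
            if name.startswith("freq") and spec is not None:
                lo, hi = spec if isinstance(spec, tuple) else (spec, spec)
                if not (0.0 <= lo and hi <= 1.0):
                    raise StratumError(
                        f"stratum {self.label!r}: {name} outside [0, 1]: {spec!r}"
                    )


def _interval(spec: FieldSpec) -> tuple[float, float] | None:
    if spec is None:
        return None
    if isinstance(spec, tuple):
        return spec
    return (spec, spec)


def _decide(
    spec: FieldSpec,
    *,
    keep_missing: bool,
    keep_low: float | None = None,
    keep_high: float | None = None,
    label: str,
    role: str,
) -> bool:
    """Does every row of the stratum survive this numeric filter?

    ``keep_low`` keeps values >= bound; ``keep_high`` keeps values <=
    bound. A range straddling the bound would make the stratum's survivor
    count stochastic, defeating the analytic ledger, so it is an error.
    """
    iv = _interval(spec)
    if iv is None:
        return keep_missing
    lo, hi = iv
    if keep_low is not None:
        if lo >= keep_low:
            return True
        if hi < keep_low:
            return False
    else:
        assert keep_high is not None
        if hi <= keep_high:
            return True
        if lo > keep_high:
            return False
    raise StratumError(
        f"stratum {label!r}: {role} range {iv!r} straddles the filter "
        "boundary; split it into unambiguous strata"
    )


def stratum_survival(
    stratum: StratumSpec, config: FilterConfig
) -> list[bool]:
    """Per-step keep decision for every row of a homogeneous stratum."""
    return [
        stratum.func_region in config.effective_exonic_keep,
        stratum.exonic_func is None
        or stratum.exonic_func not in config.exonic_func_remove,
        _decide(
            stratum.freq_1kgp,
            keep_missing=config.keep_missing_freq,
            keep_high=config.freq_threshold_1kgp,
            label=stratum.label,
            role="freq_1kgp",
        ),
        _decide(
            stratum.freq_esp6500,
            keep_missing=config.keep_missing_freq,
            keep_high=config.freq_threshold_esp,
            label=stratum.label,
            role="freq_esp6500",
        ),
        _decide(
            stratum.gerp,
            keep_missing=config.keep_missing_gerp,
            keep_low=config.gerp_min,
            label=stratum.label,
            role="gerp",
        ),
        _decide(
            stratum.fathmm,
            keep_missing=config.keep_missing_fathmm,
            keep_high=config.fathmm_max,
            label=stratum.label,
            role="fathmm",
        ),
    ]


def expectation_ledger(
    strata: Sequence[StratumSpec], config: FilterConfig | None = None
) -> dict:
    """Analytic per-step survivor counts for a stratified table.

    Computed purely from stratum definitions and the filter boundaries —
    never by running the cascade — so it serves as an independent oracle.
    """
    if config is None:
        config = FilterConfig()
    counts = [sum(s.n for s in strata)]
    per_stratum = {}
    for i in range(6):
        surviving = 0
        for s in strata:
            decisions = stratum_survival(s, config)
            if all(decisions[: i + 1]):
                surviving += s.n
        counts.append(surviving)
    for s in strata:
        per_stratum[s.label or f"stratum@{id(s)}"] = stratum_survival(s, config)
    return {"counts": counts, "per_stratum_keep": per_stratum}


def _sample(spec: FieldSpec, rng: np.random.Generator, decimals: int) -> float | None:
    if spec is None:
        return None
    if isinstance(spec, tuple):
        lo, hi = spec
        return round(float(rng.uniform(lo, hi)), decimals)
    return float(spec)


def realize_records(
    strata: Sequence[StratumSpec], seed: int
) -> list[VariantRecord]:
    """Materialize stratified rows as records, reproducibly shuffled."""
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    for s in strata:
        for _ in range(s.n):
            chrom = str(int(rng.integers(1, 23)))
            start = int(rng.integers(10_000, 50_000_000))
            is_frameshift_indel = s.exonic_func is not None and (
                "frameshift" in s.exonic_func
                and not s.exonic_func.startswith("nonframeshift")
            )
            if is_frameshift_indel and "deletion" in s.exonic_func:
                ref, alt = _BASES[int(rng.integers(4))], "-"
            elif is_frameshift_indel:
                ref, alt = "-", _BASES[int(rng.integers(4))]
            else:
                i, j = rng.choice(4, size=2, replace=False)
                ref, alt = _BASES[int(i)], _BASES[int(j)]
            gene = s.gene_pool[int(rng.integers(len(s.gene_pool)))]
            records.append(
                VariantRecord(
                    chrom=chrom,
                    start=start,
                    end=start if alt != "-" else start + 1,
                    ref=ref,
                    alt=alt,
                    func_region=s.func_region,
                    gene=gene,
                    exonic_func=s.exonic_func,
                    freq_1kgp=_sample(s.freq_1kgp, rng, 4),
                    freq_esp6500=_sample(s.freq_esp6500, rng, 4),
                    gerp=_sample(s.gerp, rng, 2),
                    fathmm=_sample(s.fathmm, rng, 2),
                )
            )
    perm = rng.permutation(len(records))
    return [records[i] for i in perm]


def make_table(
    strata: Sequence[StratumSpec],
    seed: int,
    path: str | Path | None = None,
    config: FilterConfig | None = None,
) -> tuple[list[VariantRecord], dict]:
    """Build a stratified synthetic table and its expectation ledger.

    Writes a multianno-dialect TSV when ``path`` is given. Returns the
    realized records (shuffled, as written) and the analytic ledger of
    expected survivor counts after each cascade step under ``config``
    (defaults). Deterministic under ``seed``.
    """
    if not strata:
        raise StratumError("at least one stratum is required")
    ledger = expectation_ledger(strata, config)
    records = realize_records(strata, seed)
    if path is not None:
        write_shortlist(records, path)
    return records, ledger


def causal_stratum(
    gene: str = "SPIKE1", label: str = "causal-spike-in"
) -> StratumSpec:
    """One planted causal-like variant: exonic, nonsynonymous, unobserved
    in both frequency references, conserved (GERP ≥ 0), damaging FATHMM.
    It must survive every filtration step and, given a disease map entry
    for its gene, rank first in the shortlist."""
    return StratumSpec(
        n=1,
        func_region="exonic",
        exonic_func="nonsynonymous SNV",
        freq_1kgp=None,
        freq_esp6500=None,
        gerp=4.8,
        fathmm=-3.2,
        gene_pool=(gene,),
        label=label,
    )


# Stepwise survivor counts of the framework's first published exome
# (Parkinson's disease dataset 1, individual 1): input and survivors
# after steps 1-6, then after the disease-link step.
_TABLE_SHAPE = (55_726, 19_727, 9_465, 1_281, 917, 718, 262, 252)

_GENE_POOL_MATCHED = ("CAND1", "CAND2", "CAND3")
_GENE_POOL_UNMATCHED = ("OTHER1", "OTHER2", "OTHER3", "OTHER4")
_GENE_POOL_BULK = tuple(f"BULK{i}" for i in range(1, 21))


def table_shaped_profile(scale: float = 0.1) -> list[StratumSpec]:
    """Strata reproducing the published stepwise attrition shape, scaled.

    At the default ``scale=0.1`` the table has ~5 573 rows and the cascade
    counts are the published ones divided by ten (rounded). The final
    surviving block is split into disease-matched genes and unmatched
    genes so the disease-link step also has a predictable attrition.
    """

    def sz(i: int) -> int:
        removed = _TABLE_SHAPE[i] - _TABLE_SHAPE[i + 1]
        return max(1, round(removed * scale))

    n_final = max(2, round(_TABLE_SHAPE[6] * scale))
    n_matched = max(1, round(_TABLE_SHAPE[7] * scale))
    n_unmatched = max(1, n_final - n_matched)
    return [
        StratumSpec(
            n=sz(0),
            func_region="intronic",
            exonic_func=None,
            gene_pool=_GENE_POOL_BULK,
            label="non-exonic",
        ),
        StratumSpec(
            n=sz(1),
            exonic_func="synonymous SNV",
            gene_pool=_GENE_POOL_BULK,
            label="synonymous",
        ),
        StratumSpec(
            n=sz(2),
            freq_1kgp=(0.02, 0.6),
            freq_esp6500=(0.02, 0.6),
            gerp=(0.5, 5.0),
            fathmm=(-4.0, 0.5),
            gene_pool=_GENE_POOL_BULK,
            label="common-1kgp",
        ),
        StratumSpec(
            n=sz(3),
            freq_1kgp=(0.0, 0.008),
            freq_esp6500=(0.02, 0.4),
            gerp=(0.5, 5.0),
            fathmm=(-4.0, 0.5),
            gene_pool=_GENE_POOL_BULK,
            label="common-esp-only",
        ),
        StratumSpec(
            n=sz(4),
            freq_1kgp=None,
            freq_esp6500=(0.0, 0.009),
            gerp=(-6.0, -0.1),
            fathmm=(-4.0, 0.5),
            gene_pool=_GENE_POOL_BULK,
            label="non-conserved",
        ),
        StratumSpec(
            n=sz(5),
            freq_1kgp=(0.0, 0.009),
            freq_esp6500=None,
            gerp=(0.0, 5.0),
            fathmm=(1.1, 6.0),
            gene_pool=_GENE_POOL_BULK,
            label="tolerated-fathmm",
        ),
        StratumSpec(
            n=n_matched,
            freq_1kgp=None,
            freq_esp6500=(0.0, 0.009),
            gerp=(0.0, 5.5),
            fathmm=(-5.0, 0.9),
            gene_pool=_GENE_POOL_MATCHED,
            label="survivors-disease-matched",
        ),
        StratumSpec(
            n=n_unmatched,
            freq_1kgp=(0.0, 0.009),
            freq_esp6500=None,
            gerp=(0.0, 5.5),
            fathmm=(-5.0, 0.9),
            gene_pool=_GENE_POOL_UNMATCHED,
            label="survivors-unmatched",
        ),
    ]


def make_gene_disease_map(
    genes: Sequence[str],
    disorders_per_gene: int,
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
    seed: int = 0,
    path: str | Path | None = None,
    query_terms: Iterable[str] = (),
) -> tuple[list[tuple[str, str, str]], dict]:
    """Deterministic synthetic gene–disease TSV plus a match ledger.

    Each gene receives ``disorders_per_gene`` distinct disorder phrases
    drawn from ``vocabulary``. The ledger records, for each query term,
    which genes have a disorder containing it as a whole word — computed
    here by a direct text scan so tests can compare engine matches
    against it.
    """
    if not vocabulary:
        raise StratumError("vocabulary must be non-empty")
    if disorders_per_gene > len(vocabulary):
        raise StratumError("disorders_per_gene exceeds vocabulary size")
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    for gene in genes:
        picks = rng.choice(len(vocabulary), size=disorders_per_gene, replace=False)
        for k in sorted(int(p) for p in picks):
            rows.append((gene.upper(), vocabulary[k], "custom"))

    import re as _re

    ledger: dict[str, list[str]] = {}
    for term in query_terms:
        term_l = term.strip().lower()
        pat = _re.compile(r"\b" + _re.escape(term_l) + r"\b", _re.IGNORECASE)
        ledger[term_l] = sorted(
            {g for g, d, _ in rows if pat.search(d)}
        )

    if path is not None:
        with open(path, "w") as fh:
            fh.write("gene\tdisorder\tsource\n")
            for gene, disorder, source in rows:
                fh.write(f"{gene}\t{disorder}\t{source}\n")
    return rows, {"n_genes": len(set(g for g, _, _ in rows)), "matches": ledger}


#: Disease-map rows pairing the profile's matched gene pool with disorders
#: that contain the default query keywords; unmatched pool genes absent.
def profile_disease_rows() -> list[tuple[str, str, str]]:
    return [
        ("CAND1", "early-onset parkinsonism", "omim"),
        ("CAND2", "ataxia with myoclonic epilepsy", "diseases"),
        ("CAND3", "severe intellectual disability and microcephaly", "omim"),
        ("SPIKE1", "juvenile parkinsonism, brain disorder", "custom"),
    ]


PROFILE_QUERY_TERMS = ("parkinsonism", "ataxia", "microcephaly", "brain")


def write_profile_disease_map(path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdisorder\tsource\n")
        for gene, disorder, source in profile_disease_rows():
            fh.write(f"{gene}\t{disorder}\t{source}\n")
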