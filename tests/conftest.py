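"""Shared fixtures: random record/config generators and brute-force oracles.

The oracle functions here re-derive every filter decision directly from the
rule texts (1% rarity, negative-GERP removal, FATHMM cutoff, missing-value
policy) without touching the filter engine's predicates, so engine/oracle
agreement is a genuine two-route check.
"""

from __future__ import annotations

import random

import pytest

from exosift.filter_engine import FilterConfig
from exosift.table_io import VariantRecord

FUNC_REGIONS = (
    "exonic",
    "exonic;splicing",
    "splicing",
    "intronic",
    "intergenic",
    "UTR3",
    "UTR5",
    "ncRNA_exonic",
)

EXONIC_FUNCS = (
    "nonsynonymous SNV",
    "synonymous SNV",
    "stopgain",
    "stoploss",
    "frameshift insertion",
    "frameshift deletion",
    "nonframeshift insertion",
    "nonframeshift deletion",
    "nonframeshift substitution",
    "unknown",
    None,
)

GENES = ("GENE1", "GENE2", "GENE3;GENE4", "KCNA2", "FBXO7", "SLC1A4")


def random_record(rng: random.Random) -> VariantRecord:
    """One random annotated variant with deliberate boundary mass."""

    def maybe_freq() -> float | None:
        roll = rng.random()
        if roll < 0.25:
            return None
        if roll < 0.40:  # pile on the 1% boundary region
            return rng.choice([0.01, 0.0099, 0.0101, 0.011, 0.02])
        return round(rng.random(), 4)

    def maybe_score(lo: float, hi: float, boundary: tuple[float, ...]) -> float | None:
        roll = rng.random()
        if roll < 0.25:
            return None
        if roll < 0.40:
            return rng.choice(boundary)
        return round(rng.uniform(lo, hi), 2)

    start = rng.randrange(1, 10_000_000)
    return VariantRecord(
        chrom=str(rng.randrange(1, 23)),
        start=start,
        end=start,
        ref=rng.choice("ACGT"),
        alt=rng.choice("ACGT"),
        func_region=rng.choice(FUNC_REGIONS),
        gene=rng.choice(GENES),
        exonic_func=rng.choice(EXONIC_FUNCS),
        freq_1kgp=maybe_freq(),
        freq_esp6500=maybe_freq(),
        gerp=maybe_score(-8.0, 6.0, (0.0, -0.01, 0.01)),
        fathmm=maybe_score(-6.0, 6.0, (1.0, 0.99, 1.01, -1.5)),
    )


def random_table(rng: random.Random, max_rows: int = 200) -> list[VariantRecord]:
    return [random_record(rng) for _ in range(rng.randrange(0, max_rows + 1))]


def random_config(rng: random.Random) -> FilterConfig:
    return FilterConfig(
        include_splicing=rng.random() < 0.5,
        freq_threshold_1kgp=rng.choice([0.0, 0.005, 0.01, 0.02, 0.05]),
        freq_threshold_esp=rng.choice([0.0, 0.005, 0.01, 0.02, 0.05]),
        keep_missing_freq=rng.random() < 0.7,
        gerp_min=rng.choice([-2.0, 0.0, 1.0, 2.0]),
        keep_missing_gerp=rng.random() < 0.7,
        fathmm_max=rng.choice([-1.5, 0.0, 1.0, 2.5]),
        keep_missing_fathmm=rng.random() < 0.7,
    )


def oracle_keep(record: VariantRecord, config: FilterConfig) -> bool:
    """Brute-force restatement of the six keep rules, written against the
    published rule texts rather than the engine's predicate functions."""
    keep_set = set(config.exonic_keep)
    if config.include_splicing:
        keep_set.add("splicing")
    if record.func_region not in keep_set:
        return False
    if record.exonic_func is not None and record.exonic_func in set(
        config.exonic_func_remove
    ):
        return False
    for value, threshold in (
        (record.freq_1kgp, config.freq_threshold_1kgp),
        (record.freq_esp6500, config.freq_threshold_esp),
    ):
        if value is None:
            if not config.keep_missing_freq:
                return False
        elif value > threshold:  # "1 % or less is considered to be rare"
            return False
    if record.gerp is None:
        if not config.keep_missing_gerp:
            return False
    elif record.gerp < config.gerp_min:  # negative scores removed at default 0
        return False
    if record.fathmm is None:
        if not config.keep_missing_fathmm:
            return False
    elif record.fathmm > config.fathmm_max:  # "greater than 1.0" removed
        return False
    return True


def oracle_survivors(
    records: list[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    return [r for r in records if oracle_keep(r, config)]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20160918)


@pytest.fixture
def default_config() -> FilterConfig:
    return FilterConfig()
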