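"""The six-step variant filtration cascade with attrition accounting.

The cascade reduces an annotated exome table to a shortlist of candidate
disease variants by discarding, in a fixed order:

1. variants outside exonic regions;
2. synonymous substitutions and in-frame (non-frameshift) indels —
   classes unlikely to underlie rare disease;
3. variants common in the 1000 Genomes Project (frequency > 1 %; a
   frequency of 1 % or less counts as rare, and variants with no
   frequency data at all are prioritized, i.e. kept);
4. the same 1 % rule against the ESP6500 frequency reference;
5. variants at non-conserved positions (negative GERP score; GERP > 0
   means conserved, and zero is not negative, so it survives);
6. variants FATHMM predicts tolerated (score strictly above the cutoff;
   negative FATHMM predicts damaging).

Step 7, linking surviving genes to known disorders, lives in
:mod:`exosift.disease_link`.

Steps 2–6 are pure per-record predicates, so they commute: the final
survivor set is the conjunction of all keep-predicates, and only the
intermediate attrition counts depend on the order. The order here follows
the published framework so the attrition report reads like its stepwise
breakdown table.

Missing scores and frequencies are kept by default at every step. This
generalizes the explicit missing-frequency rule to GERP and FATHMM:
frameshift indels that survive step 2 typically carry neither score, and
dropping them for lack of annotation would contradict the framework's own
results. Each ``keep_missing_*`` flag can be switched off independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import yaml

from .errors import ConfigError
from .table_io import VariantRecord

#: Default functional-region classes kept at step 1.
DEFAULT_EXONIC_KEEP = frozenset({"exonic", "exonic;splicing"})

#: Default exonic functional classes removed at step 2 (ANNOVAR vocabulary).
DEFAULT_EXONIC_FUNC_REMOVE = frozenset(
    {
        "synonymous SNV",
        "nonframeshift insertion",
        "nonframeshift deletion",
        "nonframeshift substitution",
    }
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds, keep-sets and missing-value policy for steps 1–6.

    Attributes
    ----------
    exonic_keep
        Functional-region values kept at step 1.
    include_splicing
        Adds ``"splicing"`` to ``exonic_keep``. Off by default: the
        published stepwise counts describe step 1 as exonic regions only.
    exonic_func_remove
        Exonic functional classes removed at step 2. Records with missing
        or ``"unknown"`` class are kept.
    freq_threshold_1kgp, freq_threshold_esp
        Rarity cutoffs as fractions; a variant is removed when its
        frequency is present and *strictly greater* than the threshold
        (1 % or less is rare).
    keep_missing_freq
        Keep records with no frequency annotation (the prioritization rule
        for unobserved variants).
    gerp_min
        Keep when GERP ≥ this bound. The default 0.0 removes exactly the
        negative scores.
    fathmm_max
        Keep when FATHMM ≤ this bound. Default 1.0, the cutoff the
        framework settled on after proof-of-concept tuning; the ``strict``
        preset uses −1.5, the conventional FATHMM damaging cutoff.
    keep_missing_gerp, keep_missing_fathmm
        Keep records lacking the respective score (indels usually do).
    """

    exonic_keep: frozenset[str] = DEFAULT_EXONIC_KEEP
    include_splicing: bool = False
    exonic_func_remove: frozenset[str] = DEFAULT_EXONIC_FUNC_REMOVE
    freq_threshold_1kgp: float = 0.01
    freq_threshold_esp: float = 0.01
    keep_missing_freq: bool = True
    gerp_min: float = 0.0
    keep_missing_gerp: bool = True
    fathmm_max: float = 1.0
    keep_missing_fathmm: bool = True

    def __post_init__(self) -> None:
        for name in ("freq_threshold_1kgp", "freq_threshold_esp"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name}={value!r} outside [0, 1]")
        if not self.exonic_keep:
            raise ConfigError("exonic_keep must be non-empty")
        object.__setattr__(self, "exonic_keep", frozenset(self.exonic_keep))
        object.__setattr__(
            self, "exonic_func_remove", frozenset(self.exonic_func_remove)
        )

    @property
    def effective_exonic_keep(self) -> frozenset[str]:
        if self.include_splicing:
            return self.exonic_keep | {"splicing"}
        return self.exonic_keep

    @classmethod
    def preset(cls, name: str, **overrides) -> "FilterConfig":
        """Named presets: ``default`` (FATHMM ≤ 1.0) and ``strict``
        (FATHMM ≤ −1.5). The two differ only in ``fathmm_max``."""
        if name == "default":
            return cls(**overrides)
        if name == "strict":
            overrides.setdefault("fathmm_max", -1.5)
            return cls(**overrides)
        raise ConfigError(f"unknown preset {name!r}; expected 'default' or 'strict'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exonic_keep"] = sorted(self.exonic_keep)
        d["exonic_func_remove"] = sorted(self.exonic_func_remove)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "FilterConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown filter option(s): {sorted(unknown)}")
        payload = dict(payload)
        for key in ("exonic_keep", "exonic_func_remove"):
            if key in payload:
                payload[key] = frozenset(payload[key])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: expected a mapping of filter options")
        return cls.from_dict(payload)


# ---------------------------------------------------------------------------
# Per-record keep-predicates. Each one answers: does this record survive
# the step? Missing values follow the config's keep_missing_* policy.

def keep_exonic(record: VariantRecord, config: FilterConfig) -> bool:
    return record.func_region in config.effective_exonic_keep


def keep_functional_class(record: VariantRecord, config: FilterConfig) -> bool:
    # Missing or "unknown" class is kept: only positively identified
    # synonymous/non-frameshift classes are removed.
    if record.exonic_func is None:
        return True
    return record.exonic_func not in config.exonic_func_remove


def keep_frequency(
    record: VariantRecord, config: FilterConfig, which: str
) -> bool:
    if which == "kgp":
        value, threshold = record.freq_1kgp, config.freq_threshold_1kgp
    elif which == "esp":
        value, threshold = record.freq_esp6500, config.freq_threshold_esp
    else:
        raise ConfigError(f"unknown frequency source {which!r}")
    if value is None:
        return config.keep_missing_freq
    return value <= threshold


def keep_gerp(record: VariantRecord, config: FilterConfig) -> bool:
    if record.gerp is None:
        return config.keep_missing_gerp
    return record.gerp >= config.gerp_min


def keep_fathmm(record: VariantRecord, config: FilterConfig) -> bool:
    if record.fathmm is None:
        return config.keep_missing_fathmm
    return record.fathmm <= config.fathmm_max


def filter_exonic(
    records: Iterable[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Step 1: keep only exonic-region variants."""
    return [r for r in records if keep_exonic(r, config)]


def filter_functional_class(
    records: Iterable[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Step 2: remove synonymous and non-frameshift indel classes."""
    return [r for r in records if keep_functional_class(r, config)]


def filter_frequency(
    records: Iterable[VariantRecord],
    config: FilterConfig,
    which: str = "kgp",
    threshold: float | None = None,
) -> list[VariantRecord]:
    """Steps 3–4: remove variants common in a population reference.

    ``which`` selects the source (``"kgp"`` or ``"esp"``); ``threshold``
    overrides the config's value for that source when given.
    """
    if threshold is not None:
        if not (0.0 <= threshold <= 1.0):
            raise ConfigError(f"threshold={threshold!r} outside [0, 1]")
        key = "freq_threshold_1kgp" if which == "kgp" else "freq_threshold_esp"
        config = dataclasses.replace(config, **{key: threshold})
    return [r for r in records if keep_frequency(r, config, which)]


def filter_gerp(
    records: Iterable[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Step 5: remove variants at non-conserved positions (GERP below bound)."""
    return [r for r in records if keep_gerp(r, config)]


def filter_fathmm(
    records: Iterable[VariantRecord], config: FilterConfig
) -> list[VariantRecord]:
    """Step 6: remove variants FATHMM predicts tolerated (score above cutoff)."""
    return [r for r in records if keep_fathmm(r, config)]


def passes_all(record: VariantRecord, config: FilterConfig) -> bool:
    """Conjunction of all six keep-predicates for one record."""
    return (
        keep_exonic(record, config)
        and keep_functional_class(record, config)
        and keep_frequency(record, config, "kgp")
        and keep_frequency(record, config, "esp")
        and keep_gerp(record, config)
        and keep_fathmm(record, config)
    )


def _pct(fraction: float) -> str:
    value = fraction * 100
    return f"{value:g}%"


def step_labels(config: FilterConfig) -> list[str]:
    """Human-readable step descriptions mirroring the stepwise report."""
    return [
        "Total number of variants in input",
        "STEP 1: variants assigned to exonic regions",
        "STEP 2: synonymous and non-frameshift variants removed",
        f"STEP 3: variants with 1KGP frequency > {_pct(config.freq_threshold_1kgp)} removed",
        f"STEP 4: variants with ESP6500 frequency > {_pct(config.freq_threshold_esp)} removed",
        f"STEP 5: variants with GERP score < {config.gerp_min:g} removed",
        f"STEP 6: variants with FATHMM score > {config.fathmm_max:g} removed",
    ]


@dataclass
class CascadeReport:
    """Ordered per-step attrition ledger.

    ``counts[0]`` is the input size; ``counts[i]`` the survivors after
    step *i*. ``removed[i]`` = ``counts[i] − counts[i+1]`` for the step
    that produced ``counts[i+1]``; the first entry (the input row) removes
    nothing by construction.
    """

    step_labels: list[str]
    counts: list[int]
    removed: list[int] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.step_labels) != len(self.counts):
            raise ValueError("one label per count required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if any(b > a for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("counts must be non-increasing")
        self.removed = [0] + [
            a - b for a, b in zip(self.counts, self.counts[1:])
        ]

    def append_step(self, label: str, count: int) -> None:
        self.step_labels = self.step_labels + [label]
        self.counts = self.counts + [count]
        self.__post_init__()

    def to_rows(self) -> list[tuple[str, int, int]]:
        return list(zip(self.step_labels, self.counts, self.removed))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step\tsurvivors\tremoved\n")
            for label, count, removed in self.to_rows():
                fh.write(f"{label}\t{count}\t{removed}\n")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "step_labels": self.step_labels,
                "counts": self.counts,
                "removed": self.removed,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def run_cascade(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> tuple[list[VariantRecord], CascadeReport]:
    """Apply filtration steps 1–6 in order and account for attrition.

    Returns the surviving records (original order preserved) and a
    :class:`CascadeReport` whose counts start at the input size. The
    survivor set equals the intersection of the per-step keep-sets.
    """
    if config is None:
        config = FilterConfig()
    steps: list[Callable[[list[VariantRecord]], list[VariantRecord]]] = [
        lambda rs: filter_exonic(rs, config),
        lambda rs: filter_functional_class(rs, config),
        lambda rs: filter_frequency(rs, config, "kgp"),
        lambda rs: filter_frequency(rs, config, "esp"),
        lambda rs: filter_gerp(rs, config),
        lambda rs: filter_fathmm(rs, config),
    ]
    surviving = list(records)
    counts = [len(surviving)]
    for step in steps:
        surviving = step(surviving)
        counts.append(len(surviving))
    return surviving, CascadeReport(step_labels(config), counts)
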