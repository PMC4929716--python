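"""Reading and writing annotated exome variant tables.

Annotation engines such as ANNOVAR and its web front end wANNOVAR emit one
tab-delimited row per variant, carrying the genomic locus, the gene symbol,
functional classifications, population allele frequencies (1000 Genomes,
ESP6500), a GERP conservation score and a FATHMM pathogenicity score.
Header names drifted across annotation releases (``1000g2015aug_all`` vs
``1000G_ALL`` and so on), so column resolution goes through an alias table
mapping raw headers onto a fixed set of canonical *roles*.

Missing values are a first-class state: the missing token (``"."`` by
default) and empty cells parse to ``None`` and are never coerced to zero or
any other sentinel. Downstream filters treat missing explicitly.

Coordinates are 1-based and end-inclusive, the ANNOVAR convention; no
conversion is performed because this package filters rows, it never remaps
them.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import FormatError, SchemaError

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKEN = "."

#: Canonical column roles, in shortlist output order.
ROLES: tuple[str, ...] = (
    "chrom",
    "start",
    "end",
    "ref",
    "alt",
    "func_region",
    "gene",
    "exonic_func",
    "freq_1kgp",
    "freq_esp6500",
    "gerp",
    "fathmm",
)

#: Roles that must resolve for a table to be usable at all.
MANDATORY_ROLES: tuple[str, ...] = (
    "chrom",
    "start",
    "end",
    "ref",
    "alt",
    "func_region",
    "gene",
    "exonic_func",
)

# Raw-header aliases for the wANNOVAR/ANNOVAR "multianno" dialect, matched
# case-insensitively. Header names changed across database releases; this
# table covers both the "exome summary" and "genome summary" exports.
WANNOVAR_ALIASES: dict[str, tuple[str, ...]] = {
    "chrom": ("Chr",),
    "start": ("Start",),
    "end": ("End",),
    "ref": ("Ref",),
    "alt": ("Alt",),
    "func_region": ("Func.refGene", "Func.refgene", "Func.knownGene"),
    "gene": ("Gene.refGene", "Gene.refgene", "Gene.knownGene"),
    "exonic_func": (
        "ExonicFunc.refGene",
        "ExonicFunc.refgene",
        "ExonicFunc.knownGene",
    ),
    "freq_1kgp": (
        "1000g2015aug_all",
        "1000g2014oct_all",
        "1000G_ALL",
        "1000g_all",
    ),
    "freq_esp6500": ("esp6500siv2_all", "esp6500si_all", "ESP6500_ALL"),
    "gerp": ("GERP++_RS", "gerp++gt2", "GERP_RS"),
    "fathmm": ("FATHMM_score", "FATHMM"),
}

#: Preferred raw header emitted per role when writing without a schema.
CANONICAL_HEADERS: dict[str, str] = {
    role: aliases[0] for role, aliases in WANNOVAR_ALIASES.items()
}

_GENE_SPLIT_RE = re.compile(r"[;,]")


@dataclass(frozen=True)
class AnnotationSchema:
    """Mapping from canonical column roles to raw table headers.

    Parameters
    ----------
    column_of
        Maps each resolved role (see :data:`ROLES`) to the raw header
        string as it appears in the file. Optional roles may be absent.
    dialect
        ``"wannovar_multianno"`` when headers resolved through the built-in
        alias table, ``"generic"`` for a user-supplied column map.
    missing_token
        Cell content treated as missing, in addition to the empty string.
    """

    column_of: Mapping[str, str]
    dialect: str = "wannovar_multianno"
    missing_token: str = DEFAULT_MISSING_TOKEN

    def __post_init__(self) -> None:
        unknown = set(self.column_of) - set(ROLES)
        if unknown:
            raise SchemaError(f"unknown roles in column map: {sorted(unknown)}")
        missing = [r for r in MANDATORY_ROLES if r not in self.column_of]
        if missing:
            raise SchemaError(f"mandatory roles unresolved: {missing}")
        raw = list(self.column_of.values())
        if len(raw) != len(set(raw)):
            raise SchemaError("two roles map to the same raw header")

    @property
    def mapped_roles(self) -> tuple[str, ...]:
        return tuple(r for r in ROLES if r in self.column_of)

    @classmethod
    def from_column_map(
        cls,
        column_of: Mapping[str, str],
        missing_token: str = DEFAULT_MISSING_TOKEN,
    ) -> "AnnotationSchema":
        """Build a generic-dialect schema from an explicit role→header map."""
        return cls(dict(column_of), dialect="generic", missing_token=missing_token)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnnotationSchema":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict) or "column_of" not in payload:
            raise SchemaError(f"{path}: expected a mapping with a 'column_of' key")
        return cls(
            dict(payload["column_of"]),
            dialect=payload.get("dialect", "generic"),
            missing_token=payload.get("missing_token", DEFAULT_MISSING_TOKEN),
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "dialect": self.dialect,
            "missing_token": self.missing_token,
            "column_of": dict(self.column_of),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass
class VariantRecord:
    """One annotated variant row.

    ``start``/``end`` are 1-based inclusive. ``ref``/``alt`` of ``"-"``
    denote an insertion/deletion allele, following ANNOVAR. Frequencies are
    fractions in [0, 1]. Any score or frequency may be ``None`` (missing);
    missing never compares equal to a number in the filters.
    """

    chrom: str
    start: int
    end: int
    ref: str
    alt: str
    func_region: str
    gene: str
    exonic_func: str | None = None
    freq_1kgp: float | None = None
    freq_esp6500: float | None = None
    gerp: float | None = None
    fathmm: float | None = None
    #: Unmapped columns, in file order, preserved verbatim on output.
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"start > end at {self.chrom}:{self.start}-{self.end}"
            )
        for name in ("freq_1kgp", "freq_esp6500"):
            value = getattr(self, name)
            if value is not None and not (0.0 <= value <= 1.0):
                raise FormatError(
                    f"{name}={value!r} outside [0, 1] at {self.chrom}:{self.start}"
                )

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        """Gene cell split on ';' and ',' — ANNOVAR emits multiple symbols
        at gene boundaries. The raw cell is preserved for output."""
        return tuple(
            s for s in (t.strip() for t in _GENE_SPLIT_RE.split(self.gene)) if s
        )


def detect_schema(header_row: Sequence[str]) -> AnnotationSchema:
    """Resolve a raw header row to an :class:`AnnotationSchema`.

    Headers are whitespace-stripped and matched case-insensitively against
    the wANNOVAR alias table. All mandatory roles must resolve; optional
    frequency/score roles are left unmapped when absent.

    Raises
    ------
    FormatError
        Empty header row, or duplicate headers after stripping.
    SchemaError
        One or more mandatory roles cannot be resolved.
    """
    headers = [h.strip() for h in header_row]
    if not headers or all(not h for h in headers):
        raise FormatError("empty header row")
    lowered = [h.lower() for h in headers]
    seen: set[str] = set()
    for h in lowered:
        if h in seen:
            raise FormatError(f"duplicate header {h!r}")
        seen.add(h)

    column_of: dict[str, str] = {}
    for role, aliases in WANNOVAR_ALIASES.items():
        for alias in aliases:
            try:
                idx = lowered.index(alias.lower())
            except ValueError:
                continue
            column_of[role] = headers[idx]
            break

    unresolved = [r for r in MANDATORY_ROLES if r not in column_of]
    if unresolved:
        raise SchemaError(
            f"cannot resolve mandatory column role(s) {unresolved} "
            f"from headers {headers!r}"
        )
    return AnnotationSchema(column_of, dialect="wannovar_multianno")


def _parse_float(
    token: str,
    *,
    missing_token: str,
    role: str,
    line_no: int,
    lenient: bool,
    warn_counter: list[int],
) -> float | None:
    token = token.strip()
    if token == "" or token == missing_token:
        return None
    # Locale-independent: decimal point only, no thousands separators.
    if "," in token:
        token = "\0"  # force the failure path
    try:
        return float(token)
    except ValueError:
        if lenient:
            warn_counter[0] += 1
            return None
        raise FormatError(
            f"line {line_no}: cannot parse {role} value {token!r} as a number"
        ) from None


def _parse_int(token: str, *, role: str, line_no: int) -> int:
    try:
        return int(token.strip())
    except ValueError:
        raise FormatError(
            f"line {line_no}: cannot parse {role} value {token!r} as an integer"
        ) from None


def read_table(
    path: str | Path,
    schema: AnnotationSchema | None = None,
    *,
    lenient: bool = False,
) -> list[VariantRecord]:
    """Read a tab-delimited annotated variant table into records.

    When ``schema`` is omitted it is detected from the header row. With
    ``lenient=True``, unparsable numeric cells become missing instead of
    raising; the number of such cells is logged as a warning.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: file is empty, expected a header row")
        if schema is None:
            schema = detect_schema(header)

        stripped = [h.strip() for h in header]
        try:
            index_of = {
                role: stripped.index(raw) for role, raw in schema.column_of.items()
            }
        except ValueError as exc:
            raise SchemaError(f"{path}: schema header not found in file: {exc}")
        mapped_idx = set(index_of.values())
        extra_cols = [
            (i, h) for i, h in enumerate(stripped) if i not in mapped_idx
        ]

        warn_counter = [0]
        records: list[VariantRecord] = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: line {line_no}: expected {len(header)} columns, "
                    f"found {len(row)}"
                )

            def cell(role: str) -> str:
                return row[index_of[role]]

            def opt_str(role: str) -> str | None:
                if role not in index_of:
                    return None
                token = cell(role).strip()
                if token == "" or token == schema.missing_token:
                    return None
                return token

            def opt_float(role: str) -> float | None:
                if role not in index_of:
                    return None
                return _parse_float(
                    cell(role),
                    missing_token=schema.missing_token,
                    role=role,
                    line_no=line_no,
                    lenient=lenient,
                    warn_counter=warn_counter,
                )

            records.append(
                VariantRecord(
                    chrom=cell("chrom").strip(),
                    start=_parse_int(cell("start"), role="start", line_no=line_no),
                    end=_parse_int(cell("end"), role="end", line_no=line_no),
                    ref=cell("ref").strip(),
                    alt=cell("alt").strip(),
                    func_region=cell("func_region").strip(),
                    gene=cell("gene").strip(),
                    exonic_func=opt_str("exonic_func"),
                    freq_1kgp=opt_float("freq_1kgp"),
                    freq_esp6500=opt_float("freq_esp6500"),
                    gerp=opt_float("gerp"),
                    fathmm=opt_float("fathmm"),
                    extras={h: row[i] for i, h in extra_cols},
                )
            )
        if warn_counter[0]:
            logger.warning(
                "%s: %d unparsable numeric cell(s) treated as missing",
                path,
                warn_counter[0],
            )
    return records


def _format_number(value: float) -> str:
    # repr round-trips floats and renders integers without trailing junk;
    # keeps output byte-stable across runs.
    if value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(value)


def write_shortlist(
    records: Iterable[VariantRecord],
    path: str | Path,
    schema: AnnotationSchema | None = None,
    matches: Sequence["object"] | None = None,
) -> None:
    """Write records as a tab-delimited shortlist.

    Canonical columns come first (using the schema's raw headers when
    given), passthrough extras after, missing values rendered as the
    missing token. When ``matches`` (aligned per-record disease matches,
    see :mod:`exosift.disease_link`) is supplied, three ranking columns
    are appended: ``disease_score``, ``matched_terms``,
    ``matched_disorders``. Output is byte-stable for identical input.
    """
    records = list(records)
    if matches is not None and len(matches) != len(records):
        raise ValueError("matches must align one-to-one with records")
    missing_token = schema.missing_token if schema else DEFAULT_MISSING_TOKEN

    if schema is not None:
        roles = list(schema.mapped_roles)
        role_headers = [schema.column_of[r] for r in roles]
    else:
        roles = list(ROLES)
        role_headers = [CANONICAL_HEADERS[r] for r in roles]

    extra_headers: list[str] = []
    if records:
        extra_headers = list(records[0].extras.keys())

    match_headers = (
        ["disease_score", "matched_terms", "matched_disorders"]
        if matches is not None
        else []
    )

    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(role_headers + extra_headers + match_headers)
        for i, rec in enumerate(records):
            row: list[str] = []
            for role in roles:
                value = getattr(rec, role)
                if value is None:
                    row.append(missing_token)
                elif isinstance(value, float):
                    row.append(_format_number(value))
                else:
                    row.append(str(value))
            row.extend(rec.extras.get(h, missing_token) for h in extra_headers)
            if matches is not None:
                m = matches[i]
                row.append(str(m.score))
                row.append(",".join(sorted(m.matched_terms)) or missing_token)
                row.append("; ".join(sorted(m.matched_disorders)) or missing_token)
            writer.writerow(row)


def count_vcf_records(path: str | Path) -> int:
    """Count variant records in a VCF, for provenance cross-checks only.

    The VCF is never used for annotation; this exists so a user can verify
    that an annotated table covers the same call set it was derived from.
    """
    from cyvcf2 import VCF

    return sum(1 for _ in VCF(str(path)))
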