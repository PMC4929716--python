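"""Step 7: link surviving genes to known disorders and rank by relevance.

Gene–disease knowledge comes from local tab-delimited exports in the style
of the OMIM gene map or the DISEASES database download (``gene<TAB>disorder
[<TAB>source]``); nothing is fetched from the network, and OMIM licensing
forbids shipping real data, so fixtures use synthetic maps.

Matching is deliberately lexical: a query keyword matches a disorder
description when it occurs as a case-insensitive whole word. A record's
relevance score is the number of *distinct* query keywords matched across
all disorders of all its gene symbols. Anything semantic — ontology
traversal, phenotype-similarity scoring — is out of scope: this framework
is hypothesis-free and positions itself against phenotype-driven
prioritizers, so the disease link is a final annotation aid, not a model.

Two modes:

* **annotate** (default): every record is kept; records gain a score and
  are ranked, best first, ties in original table order.
* **drop_unmatched**: records whose genes carry no disorder annotation at
  all are removed — reproducing the small step-7 attrition of the
  published stepwise counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError
from .table_io import VariantRecord

logger = logging.getLogger(__name__)

VALID_SOURCES = ("omim", "diseases", "custom")

_WS_RE = re.compile(r"\s+")


def _normalize(text: str) -> str:
    return _WS_RE.sub(" ", text.strip())


@dataclass
class GeneDiseaseMap:
    """Upper-cased gene symbol → set of (disorder description, source tag)."""

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, gene: str, disorder: str, source: str = "custom") -> None:
        gene = gene.strip().upper()
        disorder = _normalize(disorder)
        if not gene or not disorder:
            raise FormatError("gene symbol and disorder must be non-empty")
        self.entries.setdefault(gene, set()).add((disorder, source))

    def disorders_of(self, gene: str) -> set[str]:
        return {d for d, _ in self.entries.get(gene.strip().upper(), set())}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene.strip().upper() in self.entries


def load_gene_disease_map(paths: Iterable[str | Path]) -> GeneDiseaseMap:
    """Load and union one or more gene–disease TSV files.

    Each data row is ``gene<TAB>disorder`` with an optional third ``source``
    column (``omim``, ``diseases`` or ``custom``; defaults to ``custom``).
    A header row is recognized (and skipped) when its first cell is
    ``gene`` case-insensitively. Duplicate (gene, disorder) pairs collapse.
    """
    gd_map = GeneDiseaseMap()
    for path in paths:
        path = Path(path)
        n_before = sum(len(v) for v in gd_map.entries.values())
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if line_no == 1 and parts[0].strip().lower() == "gene":
                    continue
                if len(parts) < 2:
                    raise FormatError(
                        f"{path}: line {line_no}: expected at least 2 "
                        f"tab-separated columns, found {len(parts)}"
                    )
                gene, disorder = parts[0], parts[1]
                source = parts[2].strip().lower() if len(parts) > 2 else "custom"
                if source not in VALID_SOURCES:
                    raise FormatError(
                        f"{path}: line {line_no}: unknown source {source!r}"
                    )
                if not gene.strip() or not disorder.strip():
                    raise FormatError(
                        f"{path}: line {line_no}: empty gene or disorder field"
                    )
                gd_map.add(gene, disorder, source)
        n_after = sum(len(v) for v in gd_map.entries.values())
        if n_after == n_before:
            logger.warning("%s: contributed no gene-disease entries", path)
    return gd_map


@dataclass
class DiseaseMatch:
    """Keyword-relevance result for one record.

    ``score`` is the number of distinct query keywords found; it is zero
    exactly when no disorder description matched. ``annotated`` is True
    when at least one of the record's genes has *any* disorder entry,
    matched or not — that is what drop_unmatched mode keys on.
    """

    gene: str
    matched_terms: set[str] = field(default_factory=set)
    matched_disorders: set[str] = field(default_factory=set)
    annotated: bool = False

    @property
    def score(self) -> int:
        return len(self.matched_terms)


def term_matches(term: str, disorder: str) -> bool:
    """Case-insensitive whole-word occurrence of ``term`` in ``disorder``.

    Word boundaries matter: ``epilepsy`` does not match ``epileptic``.
    """
    pattern = r"\b" + re.escape(term.strip()) + r"\b"
    return re.search(pattern, disorder, flags=re.IGNORECASE) is not None


def match_diseases(
    records: Sequence[VariantRecord],
    gd_map: GeneDiseaseMap,
    query_terms: Iterable[str],
    *,
    drop_unmatched: bool = False,
) -> tuple[list[VariantRecord], list[DiseaseMatch]]:
    """Annotate each record with its disease-keyword relevance.

    Every gene symbol of a record (multi-gene cells are split) is looked
    up; matches aggregate over symbols. Returns ``(records, matches)``
    aligned one-to-one. In annotate mode the record list is returned
    unchanged; with ``drop_unmatched=True`` records whose genes have no
    disorder annotation at all are removed (with their matches).
    """
    terms = [t.strip().lower() for t in query_terms if t.strip()]
    kept_records: list[VariantRecord] = []
    kept_matches: list[DiseaseMatch] = []
    for record in records:
        match = DiseaseMatch(gene=record.gene)
        for symbol in record.gene_symbols:
            disorders = gd_map.disorders_of(symbol)
            if disorders:
                match.annotated = True
            for disorder in disorders:
                for term in terms:
                    if term_matches(term, disorder):
                        match.matched_terms.add(term)
                        match.matched_disorders.add(disorder)
        if drop_unmatched and not match.annotated:
            continue
        kept_records.append(record)
        kept_matches.append(match)
    return kept_records, kept_matches


def rank_shortlist(
    records: Sequence[VariantRecord], matches: Sequence[DiseaseMatch]
) -> tuple[list[VariantRecord], list[DiseaseMatch]]:
    """Stable sort, descending by score; ties keep original table order."""
    if len(records) != len(matches):
        raise ValueError("matches must align one-to-one with records")
    order = sorted(range(len(records)), key=lambda i: -matches[i].score)
    return [records[i] for i in order], [matches[i] for i in order]
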