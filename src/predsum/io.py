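"""Readers and writers for the package's plain-text interchange formats.

Authoritative dialect: a UTF-8, tab-delimited predication table with header
``citation_id  subject_name  subject_semtypes  predicate  object_name
object_semtypes  negated  [sentence_text]`` where semtype lists are
comma-joined and ``negated`` is 0/1.  A best-effort ``semrep_fielded`` reader
accepts pipe-delimited exports of the style
``[citation_id|]subject|semtypes|PREDICATE|object|semtypes[|extra ...]``
and tolerates unknown trailing fields.

Companion formats: a two-column ``predicate<TAB>count`` background table, a
one-intervention-per-line reference standard, a one-concept-per-line
stoplist, and a two-column ``system_term<TAB>reference_term`` alias map.
Lines starting with ``#`` are treated as comments everywhere.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from .filters import NoveltyStoplist
from .model import (
    BackgroundDistribution,
    EmptyInputError,
    FormatError,
    Predication,
    PredicationSet,
    ReferenceStandard,
    normalize_name,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

PREDICATION_COLUMNS = (
    "citation_id",
    "subject_name",
    "subject_semtypes",
    "predicate",
    "object_name",
    "object_semtypes",
    "negated",
    "sentence_text",
)

_UPPER_PREDICATE = re.compile(r"^(NEG_)?[A-Z][A-Z_]*$")


@dataclass
class ParseReport:
    """Accounting for one read: lines seen, records kept, lines skipped."""

    lines_read: int = 0
    kept: int = 0
    skipped: int = 0
    messages: list[str] = field(default_factory=list)

    def skip(self, lineno: int, reason: str) -> None:
        self.skipped += 1
        msg = f"line {lineno}: {reason}"
        self.messages.append(msg)
        logger.debug("skipping %s", msg)


def _parse_negated(token: str) -> bool:
    token = token.strip().lower()
    if token in ("0", "false", "no", ""):
        return False
    if token in ("1", "true", "yes"):
        return True
    raise ValueError(f"bad negation flag {token!r}")


def _record_from_tsv(row: list[str]) -> Predication:
    if len(row) < 7:
        raise ValueError(f"expected >=7 fields, got {len(row)}")
    return Predication(
        citation_id=row[0].strip(),
        subject_name=row[1],
        subject_semtypes=tuple(row[2].split(",")),
        predicate=row[3],
        object_name=row[4],
        object_semtypes=tuple(row[5].split(",")),
        negated=_parse_negated(row[6]),
        sentence_text=row[7] if len(row) > 7 else "",
    )


def _record_from_semrep(row: list[str]) -> Predication:
    # Optional leading citation id: present when the predicate sits in the
    # fourth slot rather than the third.
    if len(row) >= 6 and not _UPPER_PREDICATE.match(row[2].strip()) and \
            _UPPER_PREDICATE.match(row[3].strip()):
        citation_id, row = row[0].strip(), row[1:]
    else:
        citation_id = ""
    if len(row) < 5:
        raise ValueError(f"expected >=5 fields, got {len(row)}")
    predicate = row[2].strip()
    negated = predicate.upper().startswith("NEG_")
    return Predication(
        citation_id=citation_id,
        subject_name=row[0],
        subject_semtypes=tuple(row[1].split(",")),
        predicate=predicate[4:] if negated else predicate,
        object_name=row[3],
        object_semtypes=tuple(row[4].split(",")),
        negated=negated,
    )


def read_predications(
    path: PathLike, dialect: str = "tsv"
) -> tuple[PredicationSet, ParseReport]:
    """Read a predication file; malformed lines are counted and skipped.

    Returns the set and a :class:`ParseReport`.  Raises
    :class:`EmptyInputError` when no well-formed data line is present.
    """
    if dialect not in ("tsv", "semrep_fielded"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    report = ParseReport()
    records: list[Predication] = []
    with path.open(encoding="utf-8", newline="") as handle:
        if dialect == "tsv":
            reader = csv.reader(handle, delimiter="\t")
            header_seen = False
            for lineno, row in enumerate(reader, start=1):
                if not row or (row[0].startswith("#")):
                    continue
                report.lines_read += 1
                if not header_seen:
                    header_seen = True
                    if [c.strip() for c in row[:7]] != list(PREDICATION_COLUMNS[:7]):
                        raise FormatError(
                            f"{path}: bad header {row!r}; expected columns "
                            f"{PREDICATION_COLUMNS[:7]}"
                        )
                    continue
                try:
                    records.append(_record_from_tsv(row))
                    report.kept += 1
                except ValueError as exc:
                    report.skip(lineno, str(exc))
        else:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                report.lines_read += 1
                try:
                    records.append(_record_from_semrep(line.split("|")))
                    report.kept += 1
                except ValueError as exc:
                    report.skip(lineno, str(exc))
    if not records:
        raise EmptyInputError(f"{path}: no well-formed predication lines")
    return PredicationSet.from_records(records, provenance=str(path)), report


def write_predications(data: PredicationSet, path: PathLike,
                       header_comment: str = "") -> None:
    """Write the authoritative TSV dialect (round-trips with the reader)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        if header_comment:
            for line in header_comment.splitlines():
                handle.write(f"# {line}\n")
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICATION_COLUMNS)
        for rec in data:
            writer.writerow(
                [
                    rec.citation_id,
                    rec.subject_name,
                    ",".join(rec.subject_semtypes),
                    rec.predicate,
                    rec.object_name,
                    ",".join(rec.object_semtypes),
                    "1" if rec.negated else "0",
                    rec.sentence_text,
                ]
            )


def read_background(path: PathLike) -> BackgroundDistribution:
    """Read a two-column ``predicate<TAB>count`` background table."""
    path = Path(path)
    counts: dict[str, int] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            predicate, raw = parts[0].strip(), parts[1].strip()
            try:
                count = int(raw)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric count {raw!r}"
                ) from None
            if count < 0:
                raise FormatError(f"{path}:{lineno}: negative count {count}")
            counts[predicate] = counts.get(predicate, 0) + count
    if not counts:
        raise EmptyInputError(f"{path}: empty background table")
    return BackgroundDistribution(counts=counts)


def write_background(background: BackgroundDistribution, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for predicate in sorted(background.counts):
            handle.write(f"{predicate}\t{background.counts[predicate]}\n")


def read_reference_standard(
    path: PathLike, pairing_label: str = ""
) -> ReferenceStandard:
    """Read a plain-text reference standard, one intervention per line."""
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        lines = [l for l in handle if not l.startswith("#")]
    try:
        return ReferenceStandard.from_lines(lines, pairing_label=pairing_label)
    except EmptyInputError:
        raise EmptyInputError(f"{path}: no interventions") from None


def write_reference_standard(ref: ReferenceStandard, path: PathLike) -> None:
    with Path(path).open("w", encoding="utf-8") as handle:
        for name in ref.interventions:
            handle.write(name + "\n")


def read_stoplist(path: PathLike) -> NoveltyStoplist:
    """Read a one-concept-per-line stoplist."""
    with Path(path).open(encoding="utf-8") as handle:
        names = [l.strip() for l in handle if l.strip() and not l.startswith("#")]
    return NoveltyStoplist.of(names)


def read_alias_map(path: PathLike) -> dict[str, str]:
    """Read a ``system_term<TAB>reference_term`` alias map (normalized)."""
    path = Path(path)
    aliases: dict[str, str] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            aliases[normalize_name(parts[0])] = normalize_name(parts[1])
    return aliases


def read_term_table(path: PathLike) -> dict[str, int]:
    """Read a ``term<TAB>count`` table (used by the baseline summarizer)."""
    path = Path(path)
    counts: dict[str, int] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            try:
                count = int(parts[1].strip())
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric count {parts[1]!r}"
                ) from None
            if count < 1:
                raise FormatError(f"{path}:{lineno}: counts must be >= 1")
            counts[parts[0].strip()] = counts.get(parts[0].strip(), 0) + count
    if not counts:
        raise EmptyInputError(f"{path}: empty term table")
    return counts


def read_category_map(path: PathLike) -> dict[str, str]:
    """Read a ``term<TAB>category`` map for baseline category exclusion."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 fields")
            mapping[normalize_name(parts[0])] = parts[1].strip().lower()
    return mapping
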