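"""bedRMod reading, writing and validation.

bedRMod is a BED-derived, tab-delimited text format for site-level RNA
modification data: a ``#key=value`` metadata header followed by one row per
modified site.  This module implements an 11-column BED9+2 dialect::

    chrom  start  end  mod_name  score  strand  thickStart  thickEnd  itemRgb  coverage  frequency

Coordinates are 0-based half-open (BED convention).  ``frequency`` is a
decimal fraction in [0, 1]; ``score`` mirrors it as ``round(1000 * frequency)``
so genome browsers that only read BED columns still display stoichiometry.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

__all__ = [
    "BedRModHeader",
    "SiteRecord",
    "Issue",
    "parse_bedrmod",
    "write_bedrmod",
    "validate_bedrmod",
    "to_bed6",
]

#: header keys that must be present for a file to validate cleanly
REQUIRED_HEADER_KEYS = ("fileformat", "modification_type", "assembly")

N_COLUMNS = 11
VALID_STRANDS = ("+", "-", ".")


@dataclass
class Issue:
    """One parse or validation finding, tied to a 1-based line number."""

    severity: str  # "error" | "warning"
    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] line {self.line}: {self.message}"


@dataclass
class BedRModHeader:
    """Ordered ``key=value`` metadata header of a bedRMod file."""

    entries: dict[str, str] = field(default_factory=dict)

    def validate(self) -> list[Issue]:
        """Check the required-key subset; unknown keys are preserved, not flagged."""
        return [
            Issue("warning", 0, f"missing required header key '{key}'")
            for key in REQUIRED_HEADER_KEYS
            if key not in self.entries
        ]


@dataclass
class SiteRecord:
    """One site-level modification call (single-base, BED half-open)."""

    chrom: str
    start: int
    end: int
    mod_name: str
    score: int
    strand: str
    coverage: int
    frequency: float
    item_rgb: str = "0,0,0"

    @classmethod
    def from_frequency(
        cls,
        chrom: str,
        start: int,
        mod_name: str,
        coverage: int,
        frequency: float,
        strand: str = "+",
    ) -> "SiteRecord":
        """Build a single-base record with the score derived from the frequency."""
        return cls(
            chrom=chrom,
            start=start,
            end=start + 1,
            mod_name=mod_name,
            score=round(1000 * frequency),
            strand=strand,
            coverage=coverage,
            frequency=frequency,
        )

    def invariant_issues(self, line: int = 0) -> list[Issue]:
        issues: list[Issue] = []
        if self.end != self.start + 1:
            issues.append(Issue("error", line, f"end ({self.end}) != start + 1 ({self.start + 1})"))
        if self.start < 0:
            issues.append(Issue("error", line, f"negative start {self.start}"))
        if not 0.0 <= self.frequency <= 1.0:
            issues.append(Issue("error", line, f"frequency {self.frequency} outside [0, 1]"))
        elif self.score != round(1000 * self.frequency):
            issues.append(
                Issue(
                    "error",
                    line,
                    f"score {self.score} != round(1000 * {self.frequency}) = {round(1000 * self.frequency)}",
                )
            )
        if self.coverage < 0:
            issues.append(Issue("error", line, f"negative coverage {self.coverage}"))
        if self.strand not in VALID_STRANDS:
            issues.append(Issue("error", line, f"invalid strand '{self.strand}'"))
        return issues


def _parse_data_row(fields: list[str], line_no: int) -> tuple[SiteRecord | None, list[Issue]]:
    if len(fields) != N_COLUMNS:
        return None, [Issue("error", line_no, f"expected {N_COLUMNS} columns, got {len(fields)}")]
    try:
        start = int(fields[1])
        end = int(fields[2])
        score = int(fields[4])
        coverage = int(fields[9])
    except ValueError as exc:
        return None, [Issue("error", line_no, f"non-integer coordinate/score/coverage: {exc}")]
    try:
        frequency = float(fields[10])
    except ValueError:
        return None, [Issue("error", line_no, f"non-numeric frequency '{fields[10]}'")]
    if not 0.0 <= frequency <= 1.0:
        return None, [Issue("error", line_no, f"frequency {frequency} outside [0, 1]")]
    record = SiteRecord(
        chrom=fields[0],
        start=start,
        end=end,
        mod_name=fields[3],
        score=score,
        strand=fields[5],
        coverage=coverage,
        frequency=frequency,
        item_rgb=fields[8],
    )
    return record, []


def parse_bedrmod(stream: TextIO | str) -> tuple[BedRModHeader, list[SiteRecord], list[Issue]]:
    """Parse a bedRMod file into its header, data records and any issues.

    Header lines (``#key=value``) must precede data lines.  Malformed data rows
    produce error :class:`Issue`\\ s and are dropped from the record list —
    never silently: ``rows_in == len(records) + n_error_issues``.  A file with
    no header at all parses with a warning.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    header = BedRModHeader()
    records: list[SiteRecord] = []
    issues: list[Issue] = []
    in_header = True
    saw_header = False
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if not in_header:
                issues.append(Issue("warning", line_no, "header line after data section ignored"))
                continue
            saw_header = True
            body = line[1:]
            if "=" in body:
                key, _, value = body.partition("=")
                key = key.strip()
                if key in header.entries:
                    issues.append(Issue("error", line_no, f"duplicate header key '{key}'"))
                else:
                    header.entries[key] = value
            else:
                issues.append(Issue("warning", line_no, f"header line without '=': '{line}'"))
            continue
        in_header = False
        record, row_issues = _parse_data_row(line.split("\t"), line_no)
        issues.extend(row_issues)
        if record is not None:
            records.append(record)
    if not saw_header:
        issues.append(Issue("warning", 0, "file has no header section"))
    return header, records, issues


def _format_frequency(f: float) -> str:
    # shortest round-trip representation; keeps parse(write(x)) exact
    return repr(float(f))


def write_bedrmod(header: BedRModHeader, records: Iterable[SiteRecord]) -> str:
    """Serialize a header and records to bedRMod text.

    Records are written sorted by (chrom, start, mod_name, strand); output is
    deterministic.  Records violating the SiteRecord invariants are refused
    with a ValueError listing the issues.
    """
    records = list(records)
    all_issues: list[Issue] = []
    for rec in records:
        all_issues.extend(rec.invariant_issues())
    if all_issues:
        raise ValueError(
            "refusing to write invalid records: " + "; ".join(i.message for i in all_issues)
        )
    lines = [f"#{key}={value}" for key, value in header.entries.items()]
    for rec in sorted(records, key=lambda r: (r.chrom, r.start, r.mod_name, r.strand)):
        lines.append(
            "\t".join(
                (
                    rec.chrom,
                    str(rec.start),
                    str(rec.end),
                    rec.mod_name,
                    str(rec.score),
                    rec.strand,
                    str(rec.start),
                    str(rec.end),
                    rec.item_rgb,
                    str(rec.coverage),
                    _format_frequency(rec.frequency),
                )
            )
        )
    return "\n".join(lines) + "\n" if lines else ""


def validate_bedrmod(
    records: Iterable[SiteRecord],
    reference_length: int | None = None,
    header: BedRModHeader | None = None,
) -> list[Issue]:
    """Return every invariant violation found in a record list.

    Checks per-record invariants (coordinates, frequency/score mirror, strand),
    coordinates against an optional reference length, duplicate
    (chrom, start, mod_name, strand) entries, and required header keys.
    """
    records = list(records)
    issues: list[Issue] = []
    if header is not None:
        issues.extend(header.validate())
    seen: dict[tuple[str, int, str, str], int] = {}
    for idx, rec in enumerate(records, start=1):
        issues.extend(rec.invariant_issues(line=idx))
        if reference_length is not None and rec.end > reference_length:
            issues.append(
                Issue(
                    "error",
                    idx,
                    f"site [{rec.start}, {rec.end}) beyond reference length {reference_length}",
                )
            )
        key = (rec.chrom, rec.start, rec.mod_name, rec.strand)
        if key in seen:
            issues.append(
                Issue("error", idx, f"duplicate site {key} (first seen at record {seen[key]})")
            )
        else:
            seen[key] = idx
    return issues


def to_bed6(records: Iterable[SiteRecord]) -> str:
    """Export records as plain 6-column BED for genome-browser use.

    Coverage and frequency are dropped; the score column (0-1000) carries the
    stoichiometry.
    """
    lines = [
        "\t".join((r.chrom, str(r.start), str(r.end), r.mod_name, str(r.score), r.strand))
        for r in sorted(records, key=lambda r: (r.chrom, r.start))
    ]
    return "\n".join(lines) + "\n" if lines else ""
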