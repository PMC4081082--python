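"""Domain types and file I/O for the triplex identification pipeline.

All on-disk coordinates are 1-based inclusive (the convention of miRanda-style
target-site tables); all in-memory interval arithmetic is 0-based half-open.
:func:`to_zero_based` / :func:`to_one_based` are the only places where the two
conventions meet.

Sequences are RNA, 5'->3', over ``{A, C, G, U}``.  DNA input is tolerated
everywhere: ``T`` is mapped to ``U`` on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

#: Mandatory columns of the canonical target-site table dialect.
SITE_TABLE_COLUMNS = (
    "gene_id",
    "transcript_id",
    "mirna_id",
    "site_start",
    "site_end",
    "seed_start",
    "seed_end",
    "mirsvr",
    "phastcons",
)

STABILITY_TABLE_COLUMNS = (
    "gene_id",
    "mirna1_id",
    "mirna2_id",
    "d1_ps",
    "d2_ps",
    "t1_ps",
    "t2_ps",
    "group_label",
)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class TriplexKitError(Exception):
    """Base class for all package errors."""


class ParseError(TriplexKitError):
    """A file could not be parsed (malformed record, bad alphabet...)."""


class ConfigError(TriplexKitError):
    """Invalid configuration: unknown key, missing column, out-of-range value."""


class InputError(TriplexKitError):
    """Semantically invalid input (wrong strand count, empty strand...)."""


class CoordinateError(TriplexKitError):
    """An interval falls outside its reference sequence."""


class OrderingError(TriplexKitError):
    """Two sites are overlapping or mis-ordered where an order is required."""


class NumericalError(TriplexKitError):
    """A numerical routine failed to converge."""


# ---------------------------------------------------------------------------
# Coordinate conventions
# ---------------------------------------------------------------------------

def to_zero_based(start_1: int, end_1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start_1 - 1, end_1


def to_one_based(start_0: int, end_0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start_0 + 1, end_0


def normalize_rna(seq: str) -> str:
    """Upper-case and map T->U.  Raises :class:`ParseError` on other symbols."""
    out = seq.upper().replace("T", "U")
    bad = sorted(set(out) - RNA_ALPHABET)
    if bad:
        raise ParseError(f"invalid sequence symbol(s): {', '.join(bad)}")
    return out


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: ~22 nt of regulatory RNA, 5'->3'."""

    id: str
    sequence: str
    conserved: bool = True

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not 15 <= len(seq) <= 30:
            raise InputError(
                f"miRNA {self.id!r}: length {len(seq)} outside [15, 30]"
            )


@dataclass(frozen=True)
class TargetSite:
    """One predicted miRNA binding site on a 3' UTR.

    Coordinates are 1-based inclusive positions on the + strand of the
    transcript's 3' UTR; the seed-match interval lies inside the site
    interval and spans 6-8 nt.
    """

    gene_id: str
    transcript_id: str
    mirna_id: str
    site_start: int
    site_end: int
    seed_start: int
    seed_end: int
    mirsvr: float
    phastcons: float
    validated: bool = False

    def __post_init__(self) -> None:
        if not (self.site_start <= self.seed_start <= self.seed_end <= self.site_end):
            raise InputError(
                f"site {self.gene_id}/{self.mirna_id}: seed interval "
                f"[{self.seed_start},{self.seed_end}] not inside site "
                f"[{self.site_start},{self.site_end}]"
            )
        seed_len = self.seed_end - self.seed_start + 1
        if not 6 <= seed_len <= 8:
            raise InputError(
                f"site {self.gene_id}/{self.mirna_id}: seed length {seed_len} "
                "outside [6, 8]"
            )

    @property
    def seed_interval0(self) -> tuple[int, int]:
        """Seed match as a 0-based half-open interval on the UTR."""
        return to_zero_based(self.seed_start, self.seed_end)

    @property
    def site_interval0(self) -> tuple[int, int]:
        return to_zero_based(self.site_start, self.site_end)


@dataclass(frozen=True)
class TriplexCandidate:
    """An ordered (upstream, downstream) pair of target sites on one
    transcript plus the enclosing mRNA window.

    ``window_offset`` is the 1-based UTR position of the first window
    nucleotide, so UTR position = window index + window_offset (0-based
    window index, 1-based UTR position).
    """

    gene_id: str
    transcript_id: str
    upstream_site: TargetSite
    downstream_site: TargetSite
    seed_distance: int
    window_seq: str
    window_offset: int

    def __post_init__(self) -> None:
        if self.upstream_site.seed_end >= self.downstream_site.seed_start:
            raise OrderingError(
                f"candidate {self.gene_id}: upstream seed must end before "
                "downstream seed starts"
            )
        if self.seed_distance < 0:
            raise InputError("seed_distance must be >= 0")
        win_lo = self.window_offset
        win_hi = self.window_offset + len(self.window_seq) - 1
        for site in (self.upstream_site, self.downstream_site):
            if site.site_start < win_lo or site.site_end > win_hi:
                raise CoordinateError(
                    f"candidate {self.gene_id}: window [{win_lo},{win_hi}] does "
                    f"not cover site [{site.site_start},{site.site_end}]"
                )

    def utr_to_window0(self, pos_1: int) -> int:
        """Map a 1-based UTR position into a 0-based window index."""
        return pos_1 - self.window_offset

    def seed_window_interval0(self, which: int) -> tuple[int, int]:
        """0-based half-open window interval of the seed match of miRNA 1 or 2."""
        site = self.upstream_site if which == 1 else self.downstream_site
        s0, e0 = site.seed_interval0
        off = self.window_offset - 1
        return s0 - off, e0 - off


@dataclass(frozen=True)
class StabilityRecord:
    """Stability times (ps) of one triplex and its two duplexes in an MDS
    production run, as ingested from an external summary table."""

    gene_id: str
    mirna1_id: str
    mirna2_id: str
    d1: float
    d2: float
    t1: float
    t2: float
    group_label: str = ""
    potential_energy: float | None = None

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "t1", "t2"):
            if getattr(self, name) < 0:
                raise InputError(f"stability time {name} must be >= 0")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Sequences are upper-cased and T is mapped to U; ids are taken up to the
    first whitespace.  Raises :class:`ParseError` on a record with no header
    (naming the line number) or on a non-ACGU symbol.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {line.strip()[:20]!r}"
                )
            break
        else:
            raise ParseError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            seq = normalize_rna(str(rec.seq))
        except ParseError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Target-site table
# ---------------------------------------------------------------------------

def read_site_table(
    path: str | Path,
    mirna_conservation: dict[str, bool] | None = None,
) -> tuple[list[TargetSite], list[tuple[int, str]]]:
    """Read a tab-separated miRanda-style target-site table.

    Returns ``(sites, rejections)`` where ``rejections`` is a list of
    ``(row_number, reason)`` for rows violating the TargetSite invariants
    (row numbers count data rows from 1).  A missing mandatory column raises
    :class:`ConfigError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    sites: list[TargetSite] = []
    rejections: list[tuple[int, str]] = []
    has_validated = "validated" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            sites.append(
                TargetSite(
                    gene_id=str(row.gene_id),
                    transcript_id=str(row.transcript_id),
                    mirna_id=str(row.mirna_id),
                    site_start=int(row.site_start),
                    site_end=int(row.site_end),
                    seed_start=int(row.seed_start),
                    seed_end=int(row.seed_end),
                    mirsvr=float(row.mirsvr),
                    phastcons=float(row.phastcons),
                    validated=bool(row.validated) if has_validated else False,
                )
            )
        except TriplexKitError as exc:
            rejections.append((i, str(exc)))
    return sites, rejections


def write_site_table(sites: Sequence[TargetSite], path: str | Path) -> None:
    df = pd.DataFrame([asdict(s) for s in sites], columns=list(SITE_TABLE_COLUMNS) + ["validated"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Stability table
# ---------------------------------------------------------------------------

def read_stability_table(path: str | Path) -> list[StabilityRecord]:
    """Read an MDS stability-time summary (TSV, times in picoseconds)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STABILITY_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            StabilityRecord(
                gene_id=str(row.gene_id),
                mirna1_id=str(row.mirna1_id),
                mirna2_id=str(row.mirna2_id),
                d1=float(row.d1_ps),
                d2=float(row.d2_ps),
                t1=float(row.t1_ps),
                t2=float(row.t2_ps),
                group_label=str(row.group_label),
                potential_energy=(
                    float(row.potential_energy)
                    if "potential_energy" in df.columns
                    and pd.notna(row.potential_energy)
                    else None
                ),
            )
        )
    return records


def write_stability_table(records: Sequence[StabilityRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "mirna1_id": r.mirna1_id,
            "mirna2_id": r.mirna2_id,
            "d1_ps": r.d1,
            "d2_ps": r.d2,
            "t1_ps": r.t1,
            "t2_ps": r.t2,
            "group_label": r.group_label,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(STABILITY_TABLE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Generic result records
# ---------------------------------------------------------------------------

def write_results(
    records: Sequence[dict],
    path: str | Path,
    format: str = "tsv",
    columns: Sequence[str] | None = None,
) -> None:
    """Write result records (dicts sharing a schema) as TSV or JSON.

    Both dialects round-trip losslessly through :func:`read_results` for
    string/number/boolean/null values.  An empty record list still writes the
    header (TSV) or an empty array (JSON); for an empty TSV the column schema
    must be supplied via ``columns``.
    """
    if format not in ("tsv", "json"):
        raise ConfigError(f"unknown results format: {format!r}")
    if records:
        keys = list(records[0].keys())
        for rec in records[1:]:
            if list(rec.keys()) != keys:
                raise InputError("result records do not share a schema")
    else:
        keys = list(columns) if columns else []
    if format == "json":
        with open(path, "w") as fh:
            json.dump(list(records), fh, indent=2)
            fh.write("\n")
        return
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for rec in records:
            fh.write("\t".join(_tsv_cell(rec[k]) for k in keys) + "\n")


def _tsv_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _tsv_uncell(text: str):
    if text == "NA":
        return None
    if text == "true":
        return True
    if text == "false":
        return False
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError:
        return text


def read_results(path: str | Path, format: str = "tsv") -> list[dict]:
    """Inverse of :func:`write_results`."""
    if format == "json":
        with open(path) as fh:
            return json.load(fh)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty results file")
    keys = lines[0].split("\t") if lines[0] else []
    out = []
    for line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(keys):
            raise ParseError(f"{path}: row has {len(cells)} cells, expected {len(keys)}")
        out.append({k: _tsv_uncell(c) for k, c in zip(keys, cells)})
    return out
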