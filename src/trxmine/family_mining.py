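"""Candidate mining: sequence I/O, profile-hit filters and redundancy reduction.

The mining stage consumes a protein FASTA plus a tab-separated profile-search
hit table (one row per domain hit, in the style of a domain-hits table) and
whittles the candidate set down with four filters:

1. redundancy reduction to a configurable identity (default 90%),
2. best-hit E-value strictly below a cutoff (default 1e-5),
3. completeness (unambiguous start methionine AND downstream stop codon,
   consumed as annotations — the DNA scaffolds are not modelled),
4. presence of a cysteine in the hallmark CXXC active-site window.

Every decision is logged in a :class:`FilterReport` whose counts are
conservative: kept + removed per filter always sums to the input count.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import fraction_identity
from .errors import DataError, ParseError

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SequenceRecord:
    """A protein sequence with completeness annotations.

    ``has_start``/``has_stop`` record whether the source DNA scaffold carried
    an unambiguous start methionine and a downstream stop codon; they are
    inputs, never inferred from the residues.
    """

    id: str
    residues: str
    description: str = ""
    has_start: bool = True
    has_stop: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise DataError(f"sequence {self.id!r} is empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise DataError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainHit:
    """One profile-model hit on a protein.

    Coordinates are 1-based inclusive on the protein.  ``active_site_from/to``
    delimit the CXXC window when the profile match locates it; they are absent
    (None) otherwise.
    """

    seq_id: str
    model: str
    evalue: float
    ali_from: int
    ali_to: int
    active_site_from: int | None = None
    active_site_to: int | None = None

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise DataError(f"hit for {self.seq_id!r}: evalue must be > 0")
        if not (1 <= self.ali_from <= self.ali_to):
            raise DataError(
                f"hit for {self.seq_id!r}: invalid alignment span "
                f"{self.ali_from}..{self.ali_to}"
            )
        if (self.active_site_from is None) != (self.active_site_to is None):
            raise DataError(
                f"hit for {self.seq_id!r}: active-site span must give both ends"
            )


@dataclass
class FilterReport:
    """Bookkeeping for the filter cascade; counts are conservative."""

    n_input: int = 0
    n_removed_redundant: int = 0
    n_removed_evalue: int = 0
    n_removed_incomplete: int = 0
    n_removed_no_cys: int = 0
    n_kept: int = 0
    removed_ids: dict[str, list[str]] = field(default_factory=dict)
    kept_ids: list[str] = field(default_factory=list)

    def check_conservation(self) -> None:
        total = (
            self.n_kept
            + self.n_removed_redundant
            + self.n_removed_evalue
            + self.n_removed_incomplete
            + self.n_removed_no_cys
        )
        if total != self.n_input:
            raise AssertionError(
                f"filter report does not conserve sequences: "
                f"{total} accounted for, {self.n_input} input"
            )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_removed_redundant": self.n_removed_redundant,
            "n_removed_evalue": self.n_removed_evalue,
            "n_removed_incomplete": self.n_removed_incomplete,
            "n_removed_no_cys": self.n_removed_no_cys,
            "n_kept": self.n_kept,
            "removed_ids": self.removed_ids,
            "kept_ids": self.kept_ids,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# File I/O


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA into SequenceRecords, order preserved.

    The header token before the first whitespace becomes the id.  Structural
    problems (sequence data before any header, an entry with an empty body)
    raise :class:`ParseError` naming the line, which is why this reader
    tracks lines itself instead of delegating to a generic parser.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush(at_line: int) -> None:
        nonlocal header
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"entry {header!r} has an empty body", header_line)
        seq_id, _, desc = header.partition(" ")
        if seq_id in seen:
            raise ParseError(f"duplicate sequence id {seq_id!r}", header_line)
        seen.add(seq_id)
        records.append(SequenceRecord(id=seq_id, residues=seq, description=desc))
        header = None
        chunks.clear()

    lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                header_line = lineno
                if not header:
                    raise ParseError("entry with no header text", lineno)
            else:
                if header is None:
                    raise ParseError("sequence data before any '>' header", lineno)
                chunks.append(line)
        flush(lineno)
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_hit_table(path: str | Path) -> list[DomainHit]:
    """Read a tab-separated hit table.

    Expected header: ``seq_id model evalue ali_from ali_to [as_from as_to]``
    (the last two columns optional).  Coordinates are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"seq_id": str, "model": str})
    required = ["seq_id", "model", "evalue", "ali_from", "ali_to"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"hit table {path} missing columns {missing}")
    hits = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            as_from = getattr(row, "as_from", None)
            as_to = getattr(row, "as_to", None)
            as_from = None if as_from is None or pd.isna(as_from) else int(as_from)
            as_to = None if as_to is None or pd.isna(as_to) else int(as_to)
            hits.append(
                DomainHit(
                    seq_id=str(row.seq_id),
                    model=str(row.model),
                    evalue=float(row.evalue),
                    ali_from=int(row.ali_from),
                    ali_to=int(row.ali_to),
                    active_site_from=as_from,
                    active_site_to=as_to,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"bad hit record: {exc}", line=row_no) from exc
    return hits


def read_completeness(path: str | Path) -> dict[str, tuple[bool, bool]]:
    """Read a ``seq_id has_start has_stop`` TSV into a flag mapping."""
    df = pd.read_csv(path, sep="\t", dtype={"seq_id": str})
    for col in ("seq_id", "has_start", "has_stop"):
        if col not in df.columns:
            raise ParseError(f"completeness table {path} missing column {col!r}")
    return {
        str(r.seq_id): (bool(int(r.has_start)), bool(int(r.has_stop)))
        for r in df.itertuples(index=False)
    }


def apply_completeness(
    records: list[SequenceRecord], flags: dict[str, tuple[bool, bool]]
) -> list[SequenceRecord]:
    """Attach completeness flags to records (missing ids keep their defaults)."""
    for rec in records:
        if rec.id in flags:
            rec.has_start, rec.has_stop = flags[rec.id]
    return records


# ---------------------------------------------------------------------------
# Filters


def filter_by_evalue(hits: list[DomainHit], threshold: float = 1e-5) -> set[str]:
    """Ids whose best (smallest) E-value over all hits is strictly below threshold."""
    if threshold <= 0:
        raise DataError("evalue threshold must be > 0")
    best: dict[str, float] = {}
    for hit in hits:
        if hit.seq_id not in best or hit.evalue < best[hit.seq_id]:
            best[hit.seq_id] = hit.evalue
    return {sid for sid, ev in best.items() if ev < threshold}


def filter_complete(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], list[str]]:
    """Keep records with both an unambiguous start methionine and a stop codon."""
    kept, removed = [], []
    for rec in records:
        if rec.has_start and rec.has_stop:
            kept.append(rec)
        else:
            removed.append(rec.id)
    return kept, removed


_CXXC = re.compile(r"C..C")


def has_active_site_cysteine(record: SequenceRecord, hits: list[DomainHit]) -> bool:
    """True if the record's active-site window carries a cysteine.

    If a hit provides a 4-residue active-site span, the window passes when
    position 1 or position 4 is C (attacking or resolving cysteine).  Without
    a span, fall back to scanning for the C-x-x-C pattern anywhere inside the
    hit's alignment span.
    """
    if not hits:
        raise DataError(f"sequence {record.id!r} has no profile hit")
    seq = record.residues
    for hit in hits:
        if hit.active_site_from is not None:
            lo, hi = hit.active_site_from, hit.active_site_to
            if hi - lo == 3 and hi <= len(seq):
                window = seq[lo - 1 : hi]
                if window[0] == "C" or window[3] == "C":
                    return True
                continue
        span = seq[hit.ali_from - 1 : min(hit.ali_to, len(seq))]
        if _CXXC.search(span):
            return True
    return False


def filter_active_site_cysteine(
    records: list[SequenceRecord], hits: list[DomainHit]
) -> tuple[list[SequenceRecord], list[str]]:
    by_seq: dict[str, list[DomainHit]] = {}
    for hit in hits:
        by_seq.setdefault(hit.seq_id, []).append(hit)
    kept, removed = [], []
    for rec in records:
        if has_active_site_cysteine(rec, by_seq.get(rec.id, [])):
            kept.append(rec)
        else:
            removed.append(rec.id)
    return kept, removed


# ---------------------------------------------------------------------------
# Redundancy reduction


def reduce_redundancy(
    records: list[SequenceRecord], identity_threshold: float = 0.90
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are visited by decreasing length (ties broken by id); each joins
    the first earlier representative with identity >= threshold, where
    identity is exact matches over the shorter sequence length from a global
    alignment.  Returns (representatives, member id -> representative id map
    covering every input id; representatives map to themselves).
    """
    if not (0 < identity_threshold <= 1):
        raise DataError("identity threshold must be in (0, 1]")
    order = sorted(records, key=lambda r: (-len(r.residues), r.id))
    reps: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    for rec in order:
        home = None
        for rep in reps:
            if fraction_identity(rep.residues, rec.residues) >= identity_threshold:
                home = rep
                break
        if home is None:
            reps.append(rec)
            membership[rec.id] = rec.id
        else:
            membership[rec.id] = home.id
    return reps, membership


# ---------------------------------------------------------------------------
# Pipeline

DEFAULT_FILTER_ORDER = ("redundancy", "evalue", "complete", "cysteine")


def run_filter_pipeline(
    records: list[SequenceRecord],
    hits: list[DomainHit],
    evalue_threshold: float = 1e-5,
    identity_threshold: float = 0.90,
    order: tuple[str, ...] = DEFAULT_FILTER_ORDER,
) -> tuple[list[SequenceRecord], FilterReport]:
    """Chain the filters in the configured order and return kept records + report."""
    if set(order) != set(DEFAULT_FILTER_ORDER):
        raise DataError(f"filter order must be a permutation of {DEFAULT_FILTER_ORDER}")
    report = FilterReport(n_input=len(records))
    current = list(records)
    for step in order:
        if step == "redundancy":
            before = {r.id for r in current}
            current, _membership = reduce_redundancy(current, identity_threshold)
            removed = sorted(before - {r.id for r in current})
            report.n_removed_redundant = len(removed)
            report.removed_ids["redundant"] = removed
        elif step == "evalue":
            keep_ids = filter_by_evalue(hits, evalue_threshold)
            removed = [r.id for r in current if r.id not in keep_ids]
            current = [r for r in current if r.id in keep_ids]
            report.n_removed_evalue = len(removed)
            report.removed_ids["evalue"] = removed
        elif step == "complete":
            current, removed = filter_complete(current)
            report.n_removed_incomplete = len(removed)
            report.removed_ids["incomplete"] = removed
        elif step == "cysteine":
            current, removed = filter_active_site_cysteine(current, hits)
            report.n_removed_no_cys = len(removed)
            report.removed_ids["no_cys"] = removed
    report.n_kept = len(current)
    report.kept_ids = [r.id for r in current]
    report.check_conservation()
    return current, report
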