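"""Transcript records, UTR extraction and 1-based coordinate arithmetic.

All coordinates throughout the package are **1-based and inclusive**, matching
the convention of reporter-construct names such as ``CXCL8-5'(79-153)`` (a
75-bp fragment).  Off-by-one errors here would corrupt every downstream AU
statistic, so the convention is enforced in one place: :func:`subregion`.

RNA input is stored as DNA (``U`` -> ``T``); downstream AU-content statistics
treat A and T as the AU class.  ``N`` is tolerated up to 10% of a sequence and
never counts toward composition numerators.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Transcript",
    "Region",
    "UtrSet",
    "TranscriptError",
    "ParseReport",
    "normalize_seq",
    "parse_transcripts",
    "extract_utrs",
    "subregion",
    "revcomp",
    "write_transcripts",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_STOP_CODONS = {"TAA", "TAG", "TGA"}
MAX_N_FRACTION = 0.10


class TranscriptError(ValueError):
    """Raised when a record violates the transcript invariants."""


def normalize_seq(seq: str, *, max_n_fraction: float = MAX_N_FRACTION) -> str:
    """Uppercase, convert U->T and validate the alphabet.

    Sequences with more than ``max_n_fraction`` ambiguous (N) bases are
    rejected: composition statistics on mostly-ambiguous sequence are
    meaningless.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise TranscriptError(f"non-nucleotide characters {sorted(bad)!r} in sequence")
    if s and s.count("N") / len(s) > max_n_fraction:
        raise TranscriptError(
            f"sequence is {100 * s.count('N') / len(s):.1f}% N "
            f"(limit {100 * max_n_fraction:.0f}%)"
        )
    return s


@dataclass(frozen=True)
class Transcript:
    """An mRNA-space sequence with 1-based inclusive CDS coordinates."""

    id: str
    gene: str
    species: str
    seq: str
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (1 <= self.cds_start < self.cds_end <= len(self.seq)):
            raise TranscriptError(
                f"{self.id}: CDS [{self.cds_start}, {self.cds_end}] out of bounds "
                f"for sequence of length {len(self.seq)}"
            )

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start + 1

    def validate_cds(self) -> None:
        """Check multiple-of-3 length, ATG start and stop-codon end.

        Off by default at parse time: vector-derived reporter cassettes need
        not satisfy it.
        """
        if self.cds_len % 3 != 0:
            raise TranscriptError(f"{self.id}: CDS length {self.cds_len} not a multiple of 3")
        cds = self.seq[self.cds_start - 1 : self.cds_end]
        if not cds.startswith("ATG"):
            raise TranscriptError(f"{self.id}: CDS does not start with ATG")
        if cds[-3:] not in _STOP_CODONS:
            raise TranscriptError(f"{self.id}: CDS does not end with a stop codon")


@dataclass(frozen=True)
class Region:
    """A coordinate-addressed subsequence of a parent record.

    ``start``/``end`` are 1-based inclusive positions on the parent; ``seq``
    must equal the parent subsequence at those positions.
    """

    parent_id: str
    kind: str  # five_prime_utr | three_prime_utr | cds | custom
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TranscriptError(f"{self.parent_id}: region start {self.start} > end {self.end}")
        if len(self.seq) != self.end - self.start + 1:
            raise TranscriptError(
                f"{self.parent_id}: region seq length {len(self.seq)} != "
                f"span {self.end - self.start + 1}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class UtrSet:
    """The 5' and 3' UTRs of one transcript; absent UTRs are ``None``."""

    transcript_id: str
    utr5: Region | None
    utr3: Region | None


@dataclass
class ParseReport:
    """Outcome of a batch parse: valid records plus per-record errors."""

    transcripts: list[Transcript] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)  # (record id, message)

    def raise_if_errors(self) -> None:
        if self.errors:
            lines = "; ".join(f"{rid}: {msg}" for rid, msg in self.errors)
            raise TranscriptError(f"{len(self.errors)} record(s) failed validation: {lines}")


def _parse_genbank(path: str | os.PathLike) -> Iterable[tuple[str, str, str, str, int, int]]:
    for rec in SeqIO.parse(str(path), "genbank"):
        cds_feats = [f for f in rec.features if f.type == "CDS"]
        if not cds_feats:
            yield rec.id, "", "", str(rec.seq), 0, 0  # flagged downstream
            continue
        loc = cds_feats[0].location
        if len(loc.parts) != 1:
            raise TranscriptError(f"{rec.id}: multi-interval CDS joins are not supported")
        gene = cds_feats[0].qualifiers.get("gene", [""])[0]
        organism = rec.annotations.get("organism", "")
        yield rec.id, gene, organism, str(rec.seq), int(loc.start) + 1, int(loc.end)


def parse_transcripts(
    fasta: str | os.PathLike | None = None,
    cds_table: str | os.PathLike | None = None,
    genbank: str | os.PathLike | None = None,
    *,
    validate_cds: bool = False,
    strict: bool = True,
) -> ParseReport:
    """Parse transcripts from FASTA + CDS coordinate table, or a GenBank file.

    The coordinate table is tab-delimited with header columns
    ``id, gene, species, cds_start, cds_end`` and exactly one row per FASTA
    record.  With ``strict`` (default) any failing record aborts the parse;
    otherwise failures are collected in :attr:`ParseReport.errors` and valid
    records still parse.
    """
    raw: list[tuple[str, str, str, str, int, int]] = []
    report = ParseReport()

    if genbank is not None:
        raw.extend(_parse_genbank(genbank))
    else:
        if fasta is None or cds_table is None:
            raise ValueError("provide either genbank= or both fasta= and cds_table=")
        table = pd.read_csv(cds_table, sep="\t", dtype={"id": str})
        required = {"id", "gene", "species", "cds_start", "cds_end"}
        missing = required - set(table.columns)
        if missing:
            raise TranscriptError(f"CDS table missing columns: {sorted(missing)}")
        dup = table["id"][table["id"].duplicated()]
        if not dup.empty:
            raise TranscriptError(f"duplicate ids in CDS table: {sorted(dup)}")
        rows = table.set_index("id")
        for rec in SeqIO.parse(str(fasta), "fasta"):
            if rec.id not in rows.index:
                report.errors.append((rec.id, "no row in CDS coordinate table"))
                continue
            row = rows.loc[rec.id]
            raw.append(
                (rec.id, str(row["gene"]), str(row["species"]), str(rec.seq),
                 int(row["cds_start"]), int(row["cds_end"]))
            )

    for rid, gene, species, seq, cs, ce in raw:
        try:
            if ce == 0:
                raise TranscriptError("GenBank record has no CDS feature")
            t = Transcript(rid, gene, species, normalize_seq(seq), cs, ce)
            if validate_cds:
                t.validate_cds()
            report.transcripts.append(t)
        except TranscriptError as exc:
            report.errors.append((rid, str(exc)))

    if strict:
        report.raise_if_errors()
    return report


def extract_utrs(t: Transcript) -> UtrSet:
    """Split a transcript into its UTRs around the CDS.

    The 3' UTR is the region immediately after the stop codon,
    ``[cds_end+1, len(seq)]``; the 5' UTR is ``[1, cds_start-1]``.  A UTR of
    zero length is represented as ``None`` so downstream operations fail
    loudly rather than silently computing on empty sequence.
    """
    utr5 = None
    if t.cds_start > 1:
        utr5 = Region(t.id, "five_prime_utr", 1, t.cds_start - 1, t.seq[: t.cds_start - 1])
    utr3 = None
    if t.cds_end < len(t.seq):
        utr3 = Region(t.id, "three_prime_utr", t.cds_end + 1, len(t.seq), t.seq[t.cds_end :])
    return UtrSet(t.id, utr5, utr3)


def subregion(source: Region | str, start: int, end: int, *, kind: str = "custom") -> Region:
    """Extract ``[start, end]`` (1-based inclusive) relative to the source's 5' end.

    The returned region has length ``end - start + 1``.  For a :class:`Region`
    input, the output coordinates are re-mapped onto the original parent.
    """
    seq = source.seq if isinstance(source, Region) else source
    if not (1 <= start <= end <= len(seq)):
        raise TranscriptError(
            f"subregion [{start}, {end}] out of bounds for length {len(seq)} "
            f"(valid: 1 <= start <= end <= {len(seq)})"
        )
    sub = seq[start - 1 : end]
    if isinstance(source, Region):
        return Region(source.parent_id, kind, source.start + start - 1, source.start + end - 1, sub)
    return Region("anonymous", kind, start, end, sub)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, N->N)."""
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        raise TranscriptError(f"cannot reverse-complement non-nucleotide characters {sorted(bad)!r}")
    return s.translate(_COMPLEMENT)[::-1]


def write_transcripts(
    transcripts: Sequence[Transcript],
    fasta: str | os.PathLike,
    cds_table: str | os.PathLike,
) -> None:
    """Write transcripts back to FASTA plus a CDS coordinate table.

    Round-trips with :func:`parse_transcripts`: re-parsing the written files
    yields identical Transcript values.
    """
    with open(fasta, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n{t.seq}\n")
    pd.DataFrame(
        [
            {"id": t.id, "gene": t.gene, "species": t.species,
             "cds_start": t.cds_start, "cds_end": t.cds_end}
            for t in transcripts
        ]
    ).to_csv(cds_table, sep="\t", index=False)


def region_report(regions: Sequence[Region]) -> pd.DataFrame:
    """Tidy TSV-ready table of regions (id, kind, start, end, length)."""
    return pd.DataFrame(
        [
            {"id": r.parent_id, "kind": r.kind, "start": r.start, "end": r.end,
             "length": len(r)}
            for r in regions
        ]
    )
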