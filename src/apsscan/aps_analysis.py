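"""AU-content profiling, APS classification, construct building and conservation.

The central statistic is the *AU-rich proximal UTR sequence* (APS) call: a
3' UTR is APS-positive when its AU content strictly exceeds 50% over the first
100 bases immediately after the stop codon AND the UTR is at least 300 bases
long.  Both cut-offs are parameters (``threshold`` is strict ``>``; ``min_len``
is inclusive ``>=``) so the sensitivity of the rule can be explored, but the
defaults are the operative definition.

This module also provides the in-silico mutagenesis used to build reporter
UTRs (ordered insert/delete/fuse/take edit programs with full provenance), an
AUUUA-pentamer ARE scan, and conserved-block detection over homolog sets via
an internally implemented Needleman-Wunsch global aligner with deterministic
tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequence_model import Region, TranscriptError

__all__ = [
    "AUProfile",
    "APSCall",
    "ConstructSpec",
    "AREHit",
    "ConservedBlock",
    "au_fraction",
    "au_profile",
    "classify_aps",
    "apply_edits",
    "scan_are",
    "global_align",
    "find_conserved_blocks",
]

PROXIMAL_LEN = 100
AU_THRESHOLD_PERCENT = 50.0
MIN_UTR3_LEN = 300


def au_fraction(seq: str) -> float:
    """Fraction of A+T (DNA representation of A+U) bases in a sequence.

    N counts in the denominator only: ambiguous bases dilute the statistic
    rather than inflating it.
    """
    if not seq:
        raise TranscriptError("AU fraction of an empty sequence is undefined")
    s = seq.upper()
    return (s.count("A") + s.count("T")) / len(s)


@dataclass(frozen=True)
class AUProfile:
    """Sliding-window AU content along a region, plus the fixed head statistic.

    ``points`` holds one ``(window_start, au_fraction)`` pair per window that
    fits fully inside the region; ``first100_au`` is the AU fraction of the
    first ``min(100, length)`` bases, flagged when the region is shorter than
    100 nt.
    """

    region_id: str
    window: int
    step: int
    points: tuple[tuple[int, float], ...]
    first100_au: float
    short_region_flag: bool


def au_profile(region: Region | str, window: int = 100, step: int = 10) -> AUProfile:
    """Compute the sliding-window AU profile of a region.

    The last partial window is dropped; a region shorter than one window
    yields an empty ``points`` list but still carries ``first100_au``.
    """
    if window < 1 or step < 1:
        raise TranscriptError(f"window and step must be >= 1 (got {window}, {step})")
    seq = region.seq if isinstance(region, Region) else str(region)
    rid = region.parent_id if isinstance(region, Region) else "anonymous"
    if not seq:
        raise TranscriptError("cannot profile an empty region")
    # cumulative AU counts -> O(1) per window
    au = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_au = (au == ord("A")) | (au == ord("T"))
    csum = np.concatenate([[0], np.cumsum(is_au)])
    points = []
    for start in range(1, len(seq) - window + 2, step):
        frac = (csum[start - 1 + window] - csum[start - 1]) / window
        points.append((start, float(frac)))
    head = min(PROXIMAL_LEN, len(seq))
    return AUProfile(
        region_id=rid,
        window=window,
        step=step,
        points=tuple(points),
        first100_au=float(csum[head] / head),
        short_region_flag=len(seq) < PROXIMAL_LEN,
    )


@dataclass(frozen=True)
class APSCall:
    """Result of the APS classification with both criteria and evidence."""

    region_id: str
    utr3_length: int
    first100_au_percent: float
    length_ok: bool
    au_ok: bool
    is_aps_positive: bool
    proximal_len: int
    threshold_percent: float
    min_len: int
    short_region_flag: bool


def classify_aps(
    utr3: Region | str,
    proximal_len: int = PROXIMAL_LEN,
    threshold: float = AU_THRESHOLD_PERCENT,
    min_len: int = MIN_UTR3_LEN,
) -> APSCall:
    """Classify a 3' UTR as APS-positive or -negative.

    ``au_ok`` requires the proximal AU percentage to *strictly exceed*
    ``threshold``; ``length_ok`` requires the UTR length to be *at least*
    ``min_len``.  Positivity is the conjunction of the two.
    """
    seq = utr3.seq if isinstance(utr3, Region) else str(utr3)
    rid = utr3.parent_id if isinstance(utr3, Region) else "anonymous"
    if not seq:
        raise TranscriptError("cannot classify an empty 3' UTR")
    head = seq[: min(proximal_len, len(seq))]
    au_pct = 100.0 * au_fraction(head)
    length_ok = len(seq) >= min_len
    au_ok = au_pct > threshold
    return APSCall(
        region_id=rid,
        utr3_length=len(seq),
        first100_au_percent=au_pct,
        length_ok=length_ok,
        au_ok=au_ok,
        is_aps_positive=length_ok and au_ok,
        proximal_len=proximal_len,
        threshold_percent=threshold,
        min_len=min_len,
        short_region_flag=len(seq) < proximal_len,
    )


# ---------------------------------------------------------------------------
# In-silico reporter construct building


@dataclass
class ConstructSpec:
    """An ordered edit program that builds a reporter UTR from named parts.

    Edits are tuples, applied in order to the current working sequence, with
    coordinates re-evaluated after each edit:

    * ``("take", start, end)`` - keep only ``[start, end]`` (1-based inclusive)
    * ``("insert_at", pos, part_name)`` - insert a named part after position
      ``pos`` (``pos=0`` inserts before base 1)
    * ``("fuse", part_name)`` - append a named part at the 3' end
    * ``("delete", start, end)`` - remove ``[start, end]``

    The program starts from ``parts[initial]``.  Every applied edit is logged
    with the before/after sequence lengths, making the build auditable and
    replayable.
    """

    name: str
    parts: dict[str, str]
    initial: str
    edits: list[tuple] = field(default_factory=list)
    provenance_log: list[dict] = field(default_factory=list)


def _part_seq(spec: ConstructSpec, name: str) -> str:
    try:
        return spec.parts[name]
    except KeyError:
        raise TranscriptError(f"{spec.name}: unknown part {name!r}") from None


def apply_edits(spec: ConstructSpec) -> Region:
    """Replay a construct's edit program and return the resulting UTR region.

    Deterministic: the same spec always yields the same sequence.  The spec's
    ``provenance_log`` is rebuilt from scratch on every call.
    """
    seq = _part_seq(spec, spec.initial)
    spec.provenance_log = []
    for edit in spec.edits:
        op = edit[0]
        before = len(seq)
        if op == "take":
            _, start, end = edit
            if not (1 <= start <= end <= len(seq)):
                raise TranscriptError(
                    f"{spec.name}: take [{start}, {end}] out of bounds for length {len(seq)}"
                )
            seq = seq[start - 1 : end]
        elif op == "insert_at":
            _, pos, part = edit
            if not (0 <= pos <= len(seq)):
                raise TranscriptError(
                    f"{spec.name}: insert position {pos} outside [0, {len(seq)}]"
                )
            donor = _part_seq(spec, part)
            seq = seq[:pos] + donor + seq[pos:]
        elif op == "fuse":
            _, part = edit
            seq = seq + _part_seq(spec, part)
        elif op == "delete":
            _, start, end = edit
            if not (1 <= start <= end <= len(seq)):
                raise TranscriptError(
                    f"{spec.name}: delete [{start}, {end}] out of bounds for length {len(seq)}"
                )
            seq = seq[: start - 1] + seq[end:]
        else:
            raise TranscriptError(f"{spec.name}: unknown edit operation {op!r}")
        spec.provenance_log.append(
            {"op": op, "args": list(edit[1:]), "before_len": before, "after_len": len(seq)}
        )
    return Region(spec.name, "custom", 1, len(seq), seq)


# ---------------------------------------------------------------------------
# ARE scan


@dataclass(frozen=True)
class AREHit:
    """One AUUUA-pentamer occurrence (DNA representation ATTTA)."""

    region_id: str
    start: int
    end: int
    motif: str
    cluster_id: int


def scan_are(region: Region | str, pattern: str = "ATTTA", cluster_gap: int = 5) -> list[AREHit]:
    """Find all (possibly overlapping) ARE pentamer occurrences.

    Hits whose starts lie within ``cluster_gap`` nt of the previous hit share
    a cluster id — AREs act in clusters, and cluster membership matters when
    building deletion constructs.
    """
    seq = region.seq if isinstance(region, Region) else str(region)
    rid = region.parent_id if isinstance(region, Region) else "anonymous"
    hits: list[AREHit] = []
    cluster = -1
    prev_start = None
    pos = seq.find(pattern)
    while pos != -1:
        start = pos + 1
        if prev_start is None or start - prev_start > cluster_gap:
            cluster += 1
        hits.append(AREHit(rid, start, start + len(pattern) - 1, pattern, cluster))
        prev_start = start
        pos = seq.find(pattern, pos + 1)
    return hits


# ---------------------------------------------------------------------------
# Global alignment and conserved-block detection

MATCH = 1
MISMATCH = -1
GAP = -2


def global_align(
    a: str,
    b: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
) -> tuple[str, str, int]:
    """Needleman-Wunsch global alignment with a linear gap penalty.

    Returns ``(aligned_a, aligned_b, score)``.  Traceback ties are broken
    deterministically: diagonal first, then up (gap in ``b``), then left
    (gap in ``a``), so identical inputs always produce identical alignments.
    """
    if not a or not b:
        raise TranscriptError("cannot globally align an empty sequence")
    n, m = len(a), len(b)
    # score rows with numpy; vectorize over the diagonal/up terms, resolve the
    # left-gap dependency with a running scan
    prev = np.arange(m + 1, dtype=np.int64) * gap
    bs = np.frombuffer(b.encode(), dtype=np.uint8)
    rows = [prev]
    for i in range(1, n + 1):
        sub = np.where(bs == ord(a[i - 1]), match, mismatch)
        diag = prev[:-1] + sub
        up = prev[1:] + gap
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = i * gap
        best = np.maximum(diag, up)
        # left dependency: cur[j] = max(best[j-1], cur[j-1] + gap)
        run = cur[0]
        for j in range(1, m + 1):
            run = max(best[j - 1], run + gap)
            cur[j] = run
        rows.append(cur)
        prev = cur
    score = int(prev[m])

    # traceback (diag > up > left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if rows[i][j] == rows[i - 1][j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and rows[i][j] == rows[i - 1][j] + gap:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
            continue
        out_a.append("-")
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score


@dataclass(frozen=True)
class ConservedBlock:
    """A maximal run of reference columns conserved across the homolog set."""

    reference_id: str
    start: int
    end: int
    length: int
    per_column_identity: float
    species_count: int


def find_conserved_blocks(
    reference: Region | str,
    homologs: Sequence[Region | str],
    identity_threshold: float = 1.0,
    min_block_len: int = 1,
) -> list[ConservedBlock]:
    """Detect conserved blocks on a reference by pairwise global alignment.

    Each homolog is aligned to the reference; per-reference-column identity is
    the fraction of homologs whose aligned base matches the reference base
    (a gap counts as a mismatch).  Maximal runs of columns with identity >=
    ``identity_threshold`` are reported, longest first.
    """
    ref_seq = reference.seq if isinstance(reference, Region) else str(reference)
    ref_id = reference.parent_id if isinstance(reference, Region) else "reference"
    if not homologs:
        raise TranscriptError("need at least one homolog")

    n = len(ref_seq)
    match_counts = np.zeros(n, dtype=np.int64)
    for h in homologs:
        h_seq = h.seq if isinstance(h, Region) else str(h)
        aln_ref, aln_h, _ = global_align(ref_seq, h_seq)
        col = 0
        for ra, ha in zip(aln_ref, aln_h):
            if ra == "-":
                continue
            if ha == ra:
                match_counts[col] += 1
            col += 1

    identity = match_counts / len(homologs)
    ok = identity >= identity_threshold
    blocks: list[ConservedBlock] = []
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            length = j - i + 1
            if length >= min_block_len:
                blocks.append(
                    ConservedBlock(
                        reference_id=ref_id,
                        start=i + 1,
                        end=j + 1,
                        length=length,
                        per_column_identity=float(identity[i : j + 1].mean()),
                        species_count=len(homologs),
                    )
                )
            i = j + 1
        else:
            i += 1
    blocks.sort(key=lambda blk: (-blk.length, blk.start))
    return blocks
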