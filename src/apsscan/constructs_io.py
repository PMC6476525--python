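"""Declarative construct-spec files (YAML) for in-silico reporter building.

A construct file names its sequence parts (inline or drawn from a FASTA of
UTRs) and lists the ordered edits that build each reporter UTR::

    parts:
      cxcl8_utr3: ATTT...     # or {fasta: utrs.fa, id: CXCL8, start: 628, end: 1252}
      tnf_head:   GGCC...
    constructs:
      - name: cxcl8_dis_tnf
        initial: cxcl8_utr3
        edits:
          - [insert_at, 285, tnf_head]
"""

from __future__ import annotations

import os

import yaml
from Bio import SeqIO

from .aps_analysis import ConstructSpec
from .sequence_model import TranscriptError, normalize_seq


def load_construct_specs(path: str | os.PathLike) -> list[ConstructSpec]:
    """Parse a construct YAML file into :class:`ConstructSpec` objects."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "constructs" not in doc:
        raise TranscriptError(f"{path}: expected a mapping with a 'constructs' list")

    base = os.path.dirname(os.fspath(path))
    parts: dict[str, str] = {}
    for name, value in (doc.get("parts") or {}).items():
        if isinstance(value, str):
            parts[name] = normalize_seq(value)
        elif isinstance(value, dict) and "fasta" in value:
            fasta = value["fasta"]
            if not os.path.isabs(fasta):
                fasta = os.path.join(base, fasta)
            records = {r.id: str(r.seq) for r in SeqIO.parse(fasta, "fasta")}
            if value["id"] not in records:
                raise TranscriptError(f"part {name!r}: id {value['id']!r} not in {fasta}")
            seq = normalize_seq(records[value["id"]])
            if "start" in value or "end" in value:
                start, end = int(value["start"]), int(value["end"])
                if not (1 <= start <= end <= len(seq)):
                    raise TranscriptError(
                        f"part {name!r}: [{start}, {end}] out of bounds for length {len(seq)}"
                    )
                seq = seq[start - 1 : end]
            parts[name] = seq
        else:
            raise TranscriptError(f"part {name!r}: expected a sequence string or fasta mapping")

    specs = []
    for c in doc["constructs"]:
        edits = [tuple(e) for e in c.get("edits", [])]
        specs.append(ConstructSpec(name=c["name"], parts=parts, initial=c["initial"], edits=edits))
    return specs
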