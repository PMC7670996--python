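"""FASTA input and chromosome-name handling."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly soft-masked) multi-FASTA into ``{id: sequence}``.

    Sequences are uppercased; lowercase (repeat-masked) stretches are
    retained and scanned, matching a screen run with repeat filtering
    off.  Duplicate record identifiers are a hard error naming the
    identifier.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def read_fasta_names(path: str | Path) -> dict[str, str]:
    """Gene-name lookup from FASTA headers.

    The token following the record id in the description is used as the
    gene name when present (``>ENST... GENE1``); otherwise the record id
    stands in for the name.
    """
    names: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        names[rec.id] = parts[1] if len(parts) > 1 else rec.id
    return names


def normalize_chrom(name: str) -> str:
    """Map bare and chr-prefixed chromosome names to the chr dialect."""
    return name if name.startswith("chr") else f"chr{name}"
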