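"""Hoogsteen triplet code for the three intermolecular triplex motifs.

A DNA:DNA:RNA triplex forms when a single-stranded RNA stretch (the
triplex-forming oligonucleotide, TFO) lies in the major groove of duplex
DNA and hydrogen-bonds to the purine-rich strand of the duplex (the
triplex target site, TTS).  Which third-strand base can sit opposite
which duplex purine — and in which orientation the third strand runs —
defines three motifs:

* ``R`` (purine motif): third strand A/G, antiparallel to the purine
  strand; canonical triplets G·GC and A·AT.
* ``Y`` (pyrimidine motif): third strand C/T, parallel; triplets C·GC
  (requiring cytosine protonation in vivo) and T·AT.
* ``M`` (mixed motif): third strand G/T, either orientation; triplets
  G·GC and T·AT.

RNA uracil is treated as thymine throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AmbiguousBaseError(ValueError):
    """A non-ACGT(U) character where a concrete nucleotide is required."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-tolerant)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase and map RNA U to T; other characters pass through."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MotifCode:
    """One motif's alphabet, triplet table and strand orientation."""

    motif: str
    allowed_third_strand_bases: frozenset[str]
    valid_triplets: frozenset[tuple[str, str]]
    orientation: str  # "parallel" | "antiparallel" | "either"

    @property
    def orientations(self) -> tuple[str, ...]:
        if self.orientation == "either":
            return ("parallel", "antiparallel")
        return (self.orientation,)


MOTIF_CODES: dict[str, MotifCode] = {
    "R": MotifCode("R", frozenset("AG"), frozenset({("G", "G"), ("A", "A")}), "antiparallel"),
    "Y": MotifCode("Y", frozenset("CT"), frozenset({("C", "G"), ("T", "A")}), "parallel"),
    "M": MotifCode("M", frozenset("GT"), frozenset({("G", "G"), ("T", "A")}), "either"),
}

# Third-strand base that partners a given duplex purine, per motif, in the
# parallel reading frame.  Used by the synthetic generator to plant TFOs.
TFO_PARTNER: dict[str, dict[str, str]] = {
    "R": {"G": "G", "A": "A"},
    "Y": {"G": "C", "A": "T"},
    "M": {"G": "G", "A": "T"},
}


def get_motif(motif: str) -> MotifCode:
    try:
        return MOTIF_CODES[motif]
    except KeyError:
        raise ValueError(f"unknown motif {motif!r}; expected one of R, Y, M") from None


def validate_triplet(third_base: str, duplex_purine_base: str, motif: str) -> bool:
    """True iff ``third_base`` may pair the duplex purine under ``motif``.

    ``third_base`` may be an RNA base (U == T).  Raises
    :class:`AmbiguousBaseError` for characters outside {A,C,G,T,U} or a
    duplex base outside {A,G}: N is never a valid triplet partner and the
    caller must treat it as an error position explicitly.
    """
    tb = normalize(third_base)
    db = duplex_purine_base.upper()
    if tb not in "ACGT" or len(tb) != 1:
        raise AmbiguousBaseError(f"ambiguous third-strand base {third_base!r}")
    if db not in "AG":
        raise AmbiguousBaseError(f"duplex position {duplex_purine_base!r} is not a purine")
    return (tb, db) in MOTIF_CODES[motif].valid_triplets
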