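"""Pairing of TFO and TTS candidates into predicted triplex sites.

A predicted triplex site (PTS) is a gap-free alignment of a stretch of
the RNA third strand against the purine strand of a duplex target, in
the motif's orientation, where at least ``1 - max_error_rate`` of the
aligned positions form valid Hoogsteen triplets.

Orientation convention: *parallel* reads the TFO 5'->3' against the
purine strand 5'->3'; *antiparallel* reads the TFO 3'->5' against the
purine strand 5'->3'.  For the mixed motif both orientations are tried.

    antiparallel, R motif             parallel, Y motif
    TFO  3'-G A G G A-5'              TFO  5'-C T C C T-3'
    pur  5'-G A G G A-3'              pur  5'-G A G G A-3'
    (G.GC and A.AT triplets)          (C.GC and T.AT triplets)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import read_fasta, read_fasta_names
from .motifs import MOTIF_CODES, get_motif
from .search import SearchParams, TFOCandidate, TTSCandidate, find_tfo_candidates, find_tts_candidates, maximal_windows

HIT_COLUMNS = [
    "transcript_id",
    "gene_name",
    "transcript_length",
    "tfo_start",
    "tfo_stop",
    "chrom",
    "tts_start",
    "tts_stop",
    "motif",
    "strand_orientation",
    "purine_strand",
    "error_count",
    "guanine_rate",
]

# per-motif 256x256 lookup: _TRIPLET_OK[motif][ord(third), ord(purine)]
_TRIPLET_OK: dict[str, np.ndarray] = {}
for _m, _code in MOTIF_CODES.items():
    _tab = np.zeros((256, 256), dtype=bool)
    for _tb, _db in _code.valid_triplets:
        _tab[ord(_tb), ord(_db)] = True
    _TRIPLET_OK[_m] = _tab


@dataclass(frozen=True)
class TriplexHit:
    """One predicted triplex site: a TFO window paired with a TTS window."""

    transcript_id: str
    tfo_start: int
    tfo_stop: int
    chrom: str
    tts_start: int
    tts_stop: int
    motif: str
    strand_orientation: str
    purine_strand: str
    error_count: int
    guanine_rate: float

    @property
    def length(self) -> int:
        return self.tts_stop - self.tts_start

    @property
    def sort_key(self) -> tuple:
        return (
            self.chrom,
            self.tts_start,
            self.transcript_id,
            self.tfo_start,
            self.tts_stop,
            self.tfo_stop,
            self.motif,
            self.strand_orientation,
        )


def match_triplex(tfo: TFOCandidate, tts: TTSCandidate, params: SearchParams) -> list[TriplexHit]:
    """All maximal triplex alignments between one TFO and one TTS window.

    The shorter window slides across the longer at every offset; within
    each alignment, maximal sub-windows of length >= ``min_length`` with
    a triplet-violation fraction <= ``max_error_rate`` each yield one
    hit.  Duplicates (same coordinates and orientation) are emitted
    once.
    """
    code = get_motif(params.motif)
    table = _TRIPLET_OK[params.motif]
    t_seq = tfo.seq
    s_seq = tts.seq
    m, k = len(t_seq), len(s_seq)
    if min(m, k) < params.min_length:
        return []
    s_arr = np.frombuffer(s_seq.encode("ascii"), dtype=np.uint8)
    hits: dict[tuple, TriplexHit] = {}
    for orientation in code.orientations:
        t_or = t_seq[::-1] if orientation == "antiparallel" else t_seq
        t_arr = np.frombuffer(t_or.encode("ascii"), dtype=np.uint8)
        if m <= k:
            offsets = range(k - m + 1)
        else:
            offsets = range(m - k + 1)
        for off in offsets:
            if m <= k:
                ti = t_arr
                si = s_arr[off : off + m]
            else:
                ti = t_arr[off : off + k]
                si = s_arr
            good = table[ti, si]
            for a, b in maximal_windows(
                good,
                params.min_length,
                params.max_error_rate,
                max_consecutive_errors=params.max_consecutive_errors,
            ):
                if m <= k:
                    ia, ib = a, b
                    ja, jb = off + a, off + b
                else:
                    ia, ib = off + a, off + b
                    ja, jb = a, b
                if orientation == "parallel":
                    tfo_start = tfo.start + ia
                    tfo_stop = tfo.start + ib
                    sub = t_or[ia:ib]
                else:
                    tfo_start = tfo.start + m - ib
                    tfo_stop = tfo.start + m - ia
                    sub = t_or[ia:ib]
                if tts.purine_strand == "+":
                    tts_start = tts.start + ja
                    tts_stop = tts.start + jb
                else:
                    tts_start = tts.stop - jb
                    tts_stop = tts.stop - ja
                hit = TriplexHit(
                    transcript_id=tfo.transcript_id,
                    tfo_start=tfo_start,
                    tfo_stop=tfo_stop,
                    chrom=tts.chrom,
                    tts_start=tts_start,
                    tts_stop=tts_stop,
                    motif=params.motif,
                    strand_orientation=orientation,
                    purine_strand=tts.purine_strand,
                    error_count=int((~good[a:b]).sum()),
                    guanine_rate=sub.count("G") / (b - a),
                )
                hits.setdefault(hit.sort_key + (hit.purine_strand,), hit)
    return sorted(hits.values(), key=lambda h: h.sort_key)


def scan(
    lncrna_fasta: str | Path,
    genome_fasta: str | Path,
    params: SearchParams,
) -> list[TriplexHit]:
    """Screen every transcript against every chromosome for one motif.

    Chromosomes are processed independently; the result is the
    deduplicated union of :func:`match_triplex` over all candidate
    pairs, sorted by (chrom, tts_start, transcript_id, tfo_start).
    """
    transcripts = read_fasta(lncrna_fasta)
    genome = read_fasta(genome_fasta)
    tfos: dict[str, list[TFOCandidate]] = {
        tid: find_tfo_candidates(seq, params, transcript_id=tid) for tid, seq in transcripts.items()
    }
    hits: dict[tuple, TriplexHit] = {}
    for chrom in genome:
        tts_list = find_tts_candidates(genome[chrom], chrom, params)
        for tts in tts_list:
            for tid, tfo_list in tfos.items():
                for tfo in tfo_list:
                    for hit in match_triplex(tfo, tts, params):
                        hits.setdefault(hit.sort_key + (hit.purine_strand,), hit)
    return sorted(hits.values(), key=lambda h: h.sort_key)


def scan_motifs(
    lncrna_fasta: str | Path,
    genome_fasta: str | Path,
    params: SearchParams,
    motifs: tuple[str, ...] = ("R", "Y", "M"),
) -> list[TriplexHit]:
    """Run :func:`scan` for several motifs and pool the hits."""
    all_hits: list[TriplexHit] = []
    for motif in motifs:
        p = SearchParams(
            min_length=params.min_length,
            max_error_rate=params.max_error_rate,
            guanine_rate_bound=params.guanine_rate_bound,
            guanine_bound_direction=params.guanine_bound_direction,
            motif=motif,
            max_consecutive_errors=params.max_consecutive_errors,
        )
        all_hits.extend(scan(lncrna_fasta, genome_fasta, p))
    return sorted(all_hits, key=lambda h: h.sort_key)


def hits_to_frame(
    hits: list[TriplexHit],
    gene_names: dict[str, str] | None = None,
    transcript_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tabulate hits in the report column order."""
    gene_names = gene_names or {}
    transcript_lengths = transcript_lengths or {}
    rows = [
        {
            "transcript_id": h.transcript_id,
            "gene_name": gene_names.get(h.transcript_id, h.transcript_id),
            "transcript_length": transcript_lengths.get(h.transcript_id, pd.NA),
            "tfo_start": h.tfo_start,
            "tfo_stop": h.tfo_stop,
            "chrom": h.chrom,
            "tts_start": h.tts_start,
            "tts_stop": h.tts_stop,
            "motif": h.motif,
            "strand_orientation": h.strand_orientation,
            "purine_strand": h.purine_strand,
            "error_count": h.error_count,
            "guanine_rate": h.guanine_rate,
        }
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def write_hits_tsv(
    hits: list[TriplexHit],
    path: str | Path,
    lncrna_fasta: str | Path | None = None,
) -> pd.DataFrame:
    """Write the hit report TSV; returns the frame written."""
    gene_names = read_fasta_names(lncrna_fasta) if lncrna_fasta else None
    lengths = None
    if lncrna_fasta:
        lengths = {tid: len(seq) for tid, seq in read_fasta(lncrna_fasta).items()}
    frame = hits_to_frame(hits, gene_names, lengths)
    frame.to_csv(path, sep="\t", index=False)
    return frame


def write_tts_bed(hits: list[TriplexHit], path: str | Path) -> None:
    """BED6 of TTS intervals: name ``transcript:motif``, score
    ``1000 * (1 - error rate)``, strand = purine strand."""
    with open(path, "w") as fh:
        for h in hits:
            score = int(round(1000 * (1 - h.error_count / h.length)))
            fh.write(
                f"{h.chrom}\t{h.tts_start}\t{h.tts_stop}\t"
                f"{h.transcript_id}:{h.motif}\t{score}\t{h.purine_strand}\n"
            )
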