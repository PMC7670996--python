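"""Brute-force reference implementations for the triplex scanner.

Everything here enumerates windows explicitly and validates them
position by position with incremental counters — no prefix-sum
shortcuts, no anchor pruning — so it is an independent check of the
production search path.  Intended for sequences up to ~300 nt.
"""

from __future__ import annotations

EPS = 1e-9

TRIPLETS = {
    "R": {("G", "G"), ("A", "A")},
    "Y": {("C", "G"), ("T", "A")},
    "M": {("G", "G"), ("T", "A")},
}
ALPHABETS = {"R": set("AG"), "Y": set("CT"), "M": set("GT")}
ORIENTATIONS = {"R": ("antiparallel",), "Y": ("parallel",), "M": ("parallel", "antiparallel")}
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def rc(seq: str) -> str:
    return "".join(COMP.get(c, "N") for c in reversed(seq))


def brute_maximal_windows(
    good,
    min_len: int,
    rate: float,
    aux=None,
    aux_bound=None,
    aux_dir: str = "at_most",
    max_consec=None,
):
    """All maximal valid windows by exhaustive enumeration."""
    n = len(good)
    valid = set()
    for s in range(n):
        err = 0
        auxc = 0
        run = 0
        max_run = 0
        for e in range(s + 1, n + 1):
            pos = e - 1
            if good[pos]:
                run = 0
            else:
                err += 1
                run += 1
                max_run = max(max_run, run)
            if aux is not None and aux[pos]:
                auxc += 1
            length = e - s
            if length < min_len:
                continue
            if err > rate * length + EPS:
                continue
            if aux_bound is not None:
                if aux_dir == "at_most" and auxc > aux_bound * length + EPS:
                    continue
                if aux_dir == "at_least" and auxc < aux_bound * length - EPS:
                    continue
            if max_consec is not None and max_run > max_consec:
                continue
            valid.add((s, e))
    return sorted(
        (s, e)
        for s, e in valid
        if (s - 1, e) not in valid and (s, e + 1) not in valid
    )


def brute_tfo(seq: str, motif: str, min_len: int, rate: float, g_bound=None, g_dir="at_most", max_consec=None):
    seq = norm(seq)
    alphabet = ALPHABETS[motif]
    good = [c in alphabet for c in seq]
    aux = [c == "G" for c in seq]
    return brute_maximal_windows(good, min_len, rate, aux, g_bound, g_dir, max_consec)


def brute_tts(seq: str, min_len: int, rate: float, max_consec=None):
    """[(start, stop, purine_strand), ...] on + coordinates."""
    seq = norm(seq)
    out = []
    for strand, cls in (("+", set("AG")), ("-", set("CT"))):
        good = [c in cls for c in seq]
        for s, e in brute_maximal_windows(good, min_len, rate, max_consec=max_consec):
            out.append((s, e, strand))
    return sorted(out)


def brute_match(
    tfo_seq: str,
    tfo_start: int,
    tts_seq_plus: str,
    tts_start: int,
    tts_strand: str,
    motif: str,
    min_len: int,
    rate: float,
    max_consec=None,
):
    """Hit tuples (tfo_s, tfo_e, tts_s, tts_e, orientation) for one pair."""
    trip = TRIPLETS[motif]
    t_seq = norm(tfo_seq)
    s_seq = norm(tts_seq_plus) if tts_strand == "+" else rc(norm(tts_seq_plus))
    tts_stop = tts_start + len(tts_seq_plus)
    m, k = len(t_seq), len(s_seq)
    hits = set()
    if min(m, k) < min_len:
        return hits
    for orientation in ORIENTATIONS[motif]:
        t_or = t_seq[::-1] if orientation == "antiparallel" else t_seq
        n_off = abs(k - m) + 1
        for off in range(n_off):
            if m <= k:
                pairs = [(t_or[i], s_seq[off + i]) for i in range(m)]
            else:
                pairs = [(t_or[off + j], s_seq[j]) for j in range(k)]
            good = [p in trip for p in pairs]
            for a, b in brute_maximal_windows(good, min_len, rate, max_consec=max_consec):
                if m <= k:
                    ia, ib = a, b
                    ja, jb = off + a, off + b
                else:
                    ia, ib = off + a, off + b
                    ja, jb = a, b
                if orientation == "parallel":
                    tfo_s, tfo_e = tfo_start + ia, tfo_start + ib
                else:
                    tfo_s, tfo_e = tfo_start + m - ib, tfo_start + m - ia
                if tts_strand == "+":
                    tts_s, tts_e = tts_start + ja, tts_start + jb
                else:
                    tts_s, tts_e = tts_stop - jb, tts_stop - ja
                hits.add((tfo_s, tfo_e, tts_s, tts_e, orientation))
    return hits


def brute_scan(
    transcripts: dict[str, str],
    genome: dict[str, str],
    motif: str,
    min_len: int,
    rate: float,
    g_bound=None,
    g_dir: str = "at_most",
    max_consec=None,
):
    """Full brute-force screen; returns a set of hit tuples
    (transcript, tfo_s, tfo_e, chrom, tts_s, tts_e, orientation, strand)."""
    hits = set()
    for chrom, gseq in genome.items():
        gseq = norm(gseq)
        tts_windows = brute_tts(gseq, min_len, rate, max_consec)
        for tid, rseq in transcripts.items():
            rseq = norm(rseq)
            tfo_windows = brute_tfo(rseq, motif, min_len, rate, g_bound, g_dir, max_consec)
            for ts, te in tfo_windows:
                for s, e, strand in tts_windows:
                    for tfo_s, tfo_e, tts_s, tts_e, orientation in brute_match(
                        rseq[ts:te], ts, gseq[s:e], s, strand, motif, min_len, rate, max_consec
                    ):
                        hits.add((tid, tfo_s, tfo_e, chrom, tts_s, tts_e, orientation, strand))
    return hits


def hits_to_tuples(hits):
    """Production TriplexHit list -> oracle-comparable tuple set."""
    return {
        (h.transcript_id, h.tfo_start, h.tfo_stop, h.chrom, h.tts_start, h.tts_stop, h.strand_orientation, h.purine_strand)
        for h in hits
    }
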