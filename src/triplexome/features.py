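"""Mapping predicted triplex sites onto genomic features and tracks.

Intervals are 0-based half-open throughout, the BED convention.  Three
distinct mapping rules are used downstream and kept separate here:

* per-feature frequency uses >= 1 base overlap between a PTS and a
  feature interval (a PTS may count toward several tracks, once each);
* peak tracks (TFBS, Hi-C interaction domains) use *containment*: a
  peak counts only when it lies entirely within a PTS;
* metagene profiles bin the PTS midpoint relative to stranded anchors
  (TSS/TES/exon boundaries), flipping the axis for minus-strand
  anchors.

Frequencies are normalised per base and per million bases of the
track's non-overlapping footprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import normalize_chrom
from .match import TriplexHit


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    stop: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.stop}")

    @property
    def length(self) -> int:
        return self.stop - self.start


class FeatureTrack:
    """A labelled collection of genomic intervals (one annotation class)."""

    def __init__(self, label: str, intervals: list[GenomicInterval]):
        self.label = label
        self.intervals = list(intervals)
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def trees(self) -> dict[str, IntervalTree]:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(normalize_chrom(iv.chrom), IntervalTree()).addi(iv.start, iv.stop, iv)
            self._trees = trees
        return self._trees

    @property
    def total_bases(self) -> int:
        """Size of the union of the track's intervals."""
        total = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(normalize_chrom(iv.chrom), []).append((iv.start, iv.stop))
        for spans in by_chrom.values():
            spans.sort()
            cur_s, cur_e = spans[0]
            for s, e in spans[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s
        return total


def read_bed(path: str | Path, label: str | None = None) -> FeatureTrack:
    """Read BED3/BED6 into a :class:`FeatureTrack`.

    Malformed lines (too few columns, non-integer or inverted
    coordinates) raise a hard error carrying the 1-based line number.
    Lines starting with ``track``, ``browser`` or ``#`` are skipped.
    """
    label = label if label is not None else Path(path).stem
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated BED fields")
            try:
                start, stop = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if start >= stop or start < 0:
                raise ValueError(f"{path}:{lineno}: invalid interval start={start} stop={stop}")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            intervals.append(GenomicInterval(fields[0], start, stop, strand, name))
    return FeatureTrack(label, intervals)


def write_bed(track: FeatureTrack, path: str | Path) -> None:
    """Write a track as BED6 (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.stop}\t{iv.name}\t0\t{iv.strand}\n")


def hits_to_intervals(hits: list[TriplexHit]) -> list[GenomicInterval]:
    """TTS intervals of a hit list, for mapping operations."""
    return [
        GenomicInterval(h.chrom, h.tts_start, h.tts_stop, h.purine_strand, f"{h.transcript_id}:{h.motif}")
        for h in hits
    ]


def _as_intervals(pts) -> list[GenomicInterval]:
    if pts and isinstance(pts[0], TriplexHit):
        return hits_to_intervals(pts)
    return list(pts)


def count_in_features(pts, tracks: list[FeatureTrack]) -> pd.DataFrame:
    """Per-track PTS counts and per-base / per-Mb frequencies.

    A PTS is attributed to a track when its interval overlaps any track
    interval by >= 1 base; each PTS counts at most once per track but
    may count toward several tracks.  Tracks with zero footprint are
    flagged and carry undefined (NaN) frequencies.
    """
    intervals = _as_intervals(pts)
    rows = []
    for track in tracks:
        trees = track.trees
        count = sum(
            1
            for iv in intervals
            if normalize_chrom(iv.chrom) in trees and trees[normalize_chrom(iv.chrom)].overlap(iv.start, iv.stop)
        )
        bases = track.total_bases if len(track) else 0
        rows.append(
            {
                "label": track.label,
                "pts_count": count,
                "bases": bases,
                "frequency_per_base": count / bases if bases else np.nan,
                "frequency_per_Mb": count / bases * 1e6 if bases else np.nan,
                "zero_footprint": bases == 0,
            }
        )
    return pd.DataFrame(rows)


def chromosome_frequency(pts, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Per-chromosome PTS counts normalised by chromosome length."""
    intervals = _as_intervals(pts)
    counts: dict[str, int] = {normalize_chrom(c): 0 for c in chrom_sizes}
    for iv in intervals:
        chrom = normalize_chrom(iv.chrom)
        if chrom in counts:
            counts[chrom] += 1
    rows = []
    for chrom, size in chrom_sizes.items():
        key = normalize_chrom(chrom)
        rows.append(
            {
                "label": key,
                "pts_count": counts[key],
                "bases": size,
                "frequency_per_base": counts[key] / size if size else np.nan,
                "frequency_per_Mb": counts[key] / size * 1e6 if size else np.nan,
                "zero_footprint": size == 0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MetageneProfile:
    """Binned PTS density around stranded anchor points."""

    anchor: str
    window_bp: int
    bin_bp: int
    counts: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return 2 * self.window_bp // self.bin_bp

    def to_frame(self) -> pd.DataFrame:
        total = int(self.counts.sum())
        return pd.DataFrame(
            {
                "bin_start": np.arange(self.n_bins) * self.bin_bp - self.window_bp,
                "count": self.counts.astype(int),
                "density": self.counts / total if total else np.zeros_like(self.counts, dtype=float),
            }
        )


def metagene_profile(
    pts,
    anchors: list[GenomicInterval],
    window_bp: int = 2000,
    bin_bp: int = 100,
    anchor_label: str = "TSS",
) -> MetageneProfile:
    """Bin PTS midpoints around anchors.

    The offset of a PTS midpoint from a + strand anchor is
    ``mid - anchor``; minus-strand anchors flip the axis
    (``anchor - mid``).  An offset in ``[-window_bp, window_bp)``
    increments bin ``floor((offset + window_bp) / bin_bp)``.
    """
    if (2 * window_bp) % bin_bp != 0:
        raise ValueError(f"bin_bp={bin_bp} does not divide 2*window_bp={2 * window_bp}")
    intervals = _as_intervals(pts)
    n_bins = 2 * window_bp // bin_bp
    counts = np.zeros(n_bins, dtype=np.int64)
    mids: dict[str, list[int]] = {}
    for iv in intervals:
        mids.setdefault(normalize_chrom(iv.chrom), []).append((iv.start + iv.stop) // 2)
    for anchor in anchors:
        pos = anchor.start
        flip = anchor.strand == "-"
        for mid in mids.get(normalize_chrom(anchor.chrom), ()):
            off = (pos - mid) if flip else (mid - pos)
            if -window_bp <= off < window_bp:
                counts[(off + window_bp) // bin_bp] += 1
    return MetageneProfile(anchor_label, window_bp, bin_bp, counts)


def containment_overlap(peaks: FeatureTrack, pts) -> tuple[int, list[tuple[GenomicInterval, GenomicInterval]]]:
    """Peaks entirely contained within some PTS on the same chromosome.

    Returns the number of contained peaks and the matched
    (peak, containing PTS) pairs (one pair per containing PTS).
    """
    intervals = _as_intervals(pts)
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(normalize_chrom(iv.chrom), IntervalTree()).addi(iv.start, iv.stop, iv)
    pairs: list[tuple[GenomicInterval, GenomicInterval]] = []
    count = 0
    for peak in peaks:
        chrom = normalize_chrom(peak.chrom)
        containing = [
            hit.data
            for hit in trees.get(chrom, IntervalTree()).overlap(peak.start, peak.stop)
            if hit.begin <= peak.start and hit.end >= peak.stop
        ]
        if containing:
            count += 1
            for pts_iv in sorted(containing, key=lambda x: (x.start, x.stop)):
                pairs.append((peak, pts_iv))
    return count, pairs
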