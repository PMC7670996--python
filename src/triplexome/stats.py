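"""Enrichment statistics for predicted triplex sites.

The workhorse is a 2x2 chi-square test of independence without
continuity correction,

    chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),  df = 1,

applied to base-level contingency tables (is a base inside the PTS
footprint? is it inside the track?) or, on request, to region-level
tables against an explicit background region set.  A random-region
baseline estimates the genome-average PTS frequency per base by
scanning uniformly placed regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import FeatureTrack, GenomicInterval, _as_intervals
from .io import normalize_chrom, read_fasta
from .search import SearchParams, find_tts_candidates


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (in-PTS & in-track, in-PTS & out,
    out & in-track, out & out), in base or region units."""

    a: float
    b: float
    c: float
    d: float
    unit: str = "bases"

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if any(v < 0 or not np.isfinite(v) for v in vals):
            raise ValueError("contingency counts must be finite and non-negative")
        if sum(vals) <= 0:
            raise ValueError("contingency table is empty")


@dataclass(frozen=True)
class EnrichmentResult:
    chi_square: float
    df: int
    p_value: float
    direction: str  # enriched | depleted | none
    fold: float
    table: ContingencyTable2x2


def chisq_2x2(t: ContingencyTable2x2) -> EnrichmentResult:
    """Chi-square test of independence, df = 1, no continuity correction.

    Any zero margin is a hard error ("degenerate margin") — the
    statistic is undefined there.  ``fold`` is the PTS rate in the first
    row relative to the overall PTS rate; direction follows fold vs 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    margins = {"a+b": a + b, "c+d": c + d, "a+c": a + c, "b+d": b + d}
    for name, m in margins.items():
        if m == 0:
            raise ValueError(f"degenerate margin {name} == 0")
    chi2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(sps.chi2.sf(chi2, df=1))
    fold = (a / (a + b)) / ((a + c) / n)
    if fold > 1:
        direction = "enriched"
    elif fold < 1:
        direction = "depleted"
    else:
        direction = "none"
    return EnrichmentResult(float(chi2), 1, p, direction, float(fold), t)


def _merged_spans(intervals: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(normalize_chrom(iv.chrom), []).append((iv.start, iv.stop))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s > out[-1][1]:
                out.append([s, e])
            else:
                out[-1][1] = max(out[-1][1], e)
        merged[chrom] = [(s, e) for s, e in out]
    return merged


def _span_bases(spans: dict[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for chrom_spans in spans.values() for s, e in chrom_spans)


def _intersect_bases(x: dict[str, list[tuple[int, int]]], y: dict[str, list[tuple[int, int]]]) -> int:
    total = 0
    for chrom in x.keys() & y.keys():
        xi, yi = x[chrom], y[chrom]
        i = j = 0
        while i < len(xi) and j < len(yi):
            s = max(xi[i][0], yi[j][0])
            e = min(xi[i][1], yi[j][1])
            if s < e:
                total += e - s
            if xi[i][1] <= yi[j][1]:
                i += 1
            else:
                j += 1
    return total


def _overlaps_any(iv: GenomicInterval, spans: dict[str, list[tuple[int, int]]]) -> bool:
    chrom_spans = spans.get(normalize_chrom(iv.chrom), [])
    for s, e in chrom_spans:
        if s < iv.stop and iv.start < e:
            return True
    return False


def build_contingency(
    pts,
    track: FeatureTrack,
    genome_size: int | None = None,
    unit: str = "bases",
    background: FeatureTrack | None = None,
) -> ContingencyTable2x2:
    """2x2 table of PTS against a track.

    Base unit (default): cells count bases, with ``genome_size``
    anchoring the total.  Region unit: rows are the track's regions vs
    an explicitly supplied ``background`` region set, columns are
    PTS-overlapping vs not.
    """
    pts_spans = _merged_spans(_as_intervals(pts))
    if unit == "bases":
        if genome_size is None:
            raise ValueError("genome_size is required for base-unit tables")
        track_spans = _merged_spans(track.intervals)
        pts_bases = _span_bases(pts_spans)
        track_bases = _span_bases(track_spans)
        a = _intersect_bases(pts_spans, track_spans)
        b = pts_bases - a
        c = track_bases - a
        d = genome_size - pts_bases - track_bases + a
        if d < 0:
            raise ValueError("genome_size smaller than the union of PTS and track footprints")
        return ContingencyTable2x2(a, b, c, d, unit="bases")
    if unit == "regions":
        if background is None:
            raise ValueError("region-unit tables need an explicit background track")
        a = sum(1 for iv in track.intervals if _overlaps_any(iv, pts_spans))
        b = len(track.intervals) - a
        c = sum(1 for iv in background.intervals if _overlaps_any(iv, pts_spans))
        d = len(background.intervals) - c
        # rows: track vs background; columns: PTS-overlapping vs not
        return ContingencyTable2x2(a, b, c, d, unit="regions")
    raise ValueError(f"unknown unit {unit!r}")


@dataclass(frozen=True)
class RandomBaseline:
    frequency_per_base: float
    standard_error: float
    pts_count: int
    bases_scanned: int
    n_regions: int


def random_region_baseline(
    genome_fasta: str | Path,
    n_regions: int = 1000,
    region_length: int = 1000,
    seed: int = 0,
    params: SearchParams | None = None,
) -> RandomBaseline:
    """Genome-average PTS frequency from uniformly sampled regions.

    Regions are placed uniformly over all positions where a full-length
    region fits (chromosomes weighted by their number of valid starts);
    each region is scanned for TTS windows and the frequency is the
    number of windows per base scanned, with the Monte-Carlo standard
    error of the per-region frequencies.
    """
    params = params or SearchParams()
    genome = read_fasta(genome_fasta)
    rng = np.random.default_rng(seed)
    chroms = [c for c in genome if len(genome[c]) >= region_length]
    if not chroms:
        raise ValueError("no chromosome is long enough for the requested region length")
    weights = np.array([len(genome[c]) - region_length + 1 for c in chroms], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(chroms), size=n_regions, p=weights)
    per_region = np.zeros(n_regions, dtype=float)
    total = 0
    for i, ci in enumerate(picks):
        seq = genome[chroms[ci]]
        start = int(rng.integers(0, len(seq) - region_length + 1))
        count = len(find_tts_candidates(seq[start : start + region_length], chroms[ci], params))
        per_region[i] = count / region_length
        total += count
    se = float(per_region.std(ddof=1) / np.sqrt(n_regions)) if n_regions > 1 else float("nan")
    return RandomBaseline(
        frequency_per_base=float(per_region.mean()),
        standard_error=se,
        pts_count=total,
        bases_scanned=n_regions * region_length,
        n_regions=n_regions,
    )


def compare_gene_classes(
    pts, promoters_class_a: FeatureTrack, promoters_class_b: FeatureTrack
) -> EnrichmentResult:
    """Chi-square contrast of PTS coverage between two promoter classes.

    Bases of each class are split by PTS overlap; direction "enriched"
    means class A promoters carry proportionally more PTS-covered bases
    than class B.
    """
    pts_spans = _merged_spans(_as_intervals(pts))
    a_spans = _merged_spans(promoters_class_a.intervals)
    b_spans = _merged_spans(promoters_class_b.intervals)
    a_cov = _intersect_bases(pts_spans, a_spans)
    b_cov = _intersect_bases(pts_spans, b_spans)
    a_tot = _span_bases(a_spans)
    b_tot = _span_bases(b_spans)
    table = ContingencyTable2x2(a_cov, a_tot - a_cov, b_cov, b_tot - b_cov, unit="bases")
    return chisq_2x2(table)


def enrichment_table(
    pts, tracks: list[FeatureTrack], genome_size: int
) -> pd.DataFrame:
    """Per-track base-unit enrichment with BH-adjusted q-values.

    Tracks whose table has a degenerate margin are reported with NaN
    statistics rather than aborting the batch.
    """
    rows = []
    for track in tracks:
        row = {"track_label": track.label}
        try:
            t = build_contingency(pts, track, genome_size=genome_size)
            res = chisq_2x2(t)
            row.update(
                a=t.a, b=t.b, c=t.c, d=t.d,
                chi_square=res.chi_square, p=res.p_value,
                fold=res.fold, direction=res.direction,
            )
        except ValueError as exc:
            row.update(a=np.nan, b=np.nan, c=np.nan, d=np.nan,
                       chi_square=np.nan, p=np.nan, fold=np.nan,
                       direction=f"undefined ({exc})")
        rows.append(row)
    frame = pd.DataFrame(rows)
    mask = frame["p"].notna()
    frame["q_value"] = np.nan
    if mask.any():
        frame.loc[mask, "q_value"] = multipletests(frame.loc[mask, "p"], method="fdr_bh")[1]
    return frame
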