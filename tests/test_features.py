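import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from triplexome.features import (
    FeatureTrack,
    GenomicInterval,
    chromosome_frequency,
    containment_overlap,
    count_in_features,
    metagene_profile,
    read_bed,
    write_bed,
)


def iv(chrom, start, stop, strand=".", name=""):
    return GenomicInterval(chrom, start, stop, strand, name)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=10_000, max_len=200):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span))
        out.append(iv(str(rng.choice(chroms)), start, start + int(rng.integers(1, max_len)), name=f"iv{i}"))
    return out


# --- BED I/O ----------------------------------------------------------------


def test_read_bed6_line(tmp_path):
    path = tmp_path / "a.bed"
    path.write_text("chr1\t10\t20\tx\t0\t+\n")
    track = read_bed(path)
    assert track.intervals == [iv("chr1", 10, 20, "+", "x")]


def test_read_empty_bed(tmp_path):
    path = tmp_path / "e.bed"
    path.write_text("")
    assert len(read_bed(path)) == 0


@pytest.mark.parametrize(
    "line,message",
    [
        ("chr1\t20\t10\tx", "invalid interval"),
        ("chr1\t5\tten", "non-integer"),
        ("chr1 5", "expected >= 3"),
    ],
)
def test_malformed_bed_reports_line_number(tmp_path, line, message):
    path = tmp_path / "bad.bed"
    path.write_text("chr1\t1\t2\n" + line + "\n")
    with pytest.raises(ValueError, match=f"2: .*{message}|{message}"):
        read_bed(path)


def test_bed_round_trip_identity(rng, tmp_path):
    track = FeatureTrack("fuzz", random_intervals(rng, 1000))
    path = tmp_path / "rt.bed"
    write_bed(track, path)
    again = read_bed(path, label="fuzz")
    assert again.intervals == track.intervals


# --- frequencies ------------------------------------------------------------


def test_promoter_frequency_arithmetic():
    promoter = FeatureTrack("promoter", [iv("chr1", 0, 2_000_000)])
    pts = [iv("chr1", i * 1000, i * 1000 + 40) for i in range(10)]
    table = count_in_features(pts, [promoter])
    row = table.iloc[0]
    assert row.pts_count == 10 and row.bases == 2_000_000
    assert row.frequency_per_Mb == pytest.approx(5.0)
    assert row.frequency_per_base == pytest.approx(5e-6)


def test_pts_outside_all_tracks_contributes_nowhere():
    track = FeatureTrack("cds", [iv("chr1", 100, 200)])
    table = count_in_features([iv("chr1", 500, 540), iv("chr2", 100, 140)], [track])
    assert table.iloc[0].pts_count == 0


def test_zero_footprint_track_is_flagged_not_divided():
    table = count_in_features([iv("chr1", 0, 10)], [FeatureTrack("empty", [])])
    row = table.iloc[0]
    assert bool(row.zero_footprint) and np.isnan(row.frequency_per_Mb)


def test_count_in_features_matches_quadratic_oracle(rng):
    pts = random_intervals(rng, 300)
    tracks = [FeatureTrack(f"t{j}", random_intervals(rng, 50)) for j in range(4)]
    table = count_in_features(pts, tracks)
    for j, track in enumerate(tracks):
        expected = sum(
            1
            for p in pts
            if any(p.chrom == q.chrom and p.start < q.stop and q.start < p.stop for q in track.intervals)
        )
        assert table.iloc[j].pts_count == expected


def test_frequency_invariant_under_interval_splitting():
    whole = FeatureTrack("w", [iv("chr1", 0, 1000)])
    split = FeatureTrack("s", [iv("chr1", 0, 400), iv("chr1", 400, 1000)])
    pts = [iv("chr1", 100, 140), iv("chr1", 700, 740)]
    a = count_in_features(pts, [whole]).iloc[0]
    b = count_in_features(pts, [split]).iloc[0]
    assert a.frequency_per_Mb == b.frequency_per_Mb and a.bases == b.bases


def test_chromosome_frequency():
    pts = [iv("chr1", 0, 10), iv("chr1", 50, 60), iv("chr1", 900, 940), iv("chr2", 5, 15)]
    table = chromosome_frequency(pts[:3], {"chr1": 1000, "chr2": 500})
    by = {r.label: r for r in table.itertuples()}
    assert by["chr1"].frequency_per_base == pytest.approx(0.003)
    assert by["chr2"].pts_count == 0 and by["chr2"].frequency_per_base == 0


def test_partition_counts_sum_to_total():
    tracks = [FeatureTrack("a", [iv("chr1", 0, 500)]), FeatureTrack("b", [iv("chr1", 500, 1000)])]
    pts = [iv("chr1", s, s + 10) for s in range(0, 980, 37)]
    table = count_in_features(pts, tracks)
    assert table.pts_count.sum() == len(pts)  # disjoint tracks partitioning all PTS


# --- metagene ---------------------------------------------------------------


def test_metagene_bin_arithmetic_plus_and_minus():
    pts = [iv("chr1", 1000, 1020)]  # midpoint 1010
    plus = metagene_profile(pts, [iv("chr1", 1000, 1001, "+")], window_bp=2000, bin_bp=100)
    assert plus.counts[20] == 1 and plus.counts.sum() == 1
    minus = metagene_profile(pts, [iv("chr1", 1000, 1001, "-")], window_bp=2000, bin_bp=100)
    assert minus.counts[19] == 1 and minus.counts.sum() == 1


def test_metagene_bin_must_divide_window():
    with pytest.raises(ValueError, match="does not divide"):
        metagene_profile([], [], window_bp=2000, bin_bp=300)


def test_metagene_total_equals_in_window_pairs(rng):
    pts = random_intervals(rng, 200, chroms=("chr1",), span=20_000, max_len=50)
    anchors = [iv("chr1", int(p), int(p) + 1, str(s)) for p, s in zip(rng.integers(0, 20_000, 20), rng.choice(["+", "-"], 20))]
    prof = metagene_profile(pts, anchors, window_bp=1000, bin_bp=50)
    expected = sum(
        1
        for a in anchors
        for p in pts
        if -1000 <= ((p.start + p.stop) // 2 - a.start) * (1 if a.strand == "+" else -1) < 1000
    )
    assert prof.counts.sum() == expected
    frame = prof.to_frame()
    assert frame["count"].sum() == expected and len(frame) == prof.n_bins


def test_metagene_uniform_null_is_flat(rng):
    """Uniform random PTS give a flat profile: the chi-square
    goodness-of-fit test against uniformity does not reject."""
    from scipy import stats as sps

    n = 20_000
    starts = rng.integers(0, 4000, n)
    pts = [iv("chr1", int(s), int(s) + 2) for s in starts]
    prof = metagene_profile(pts, [iv("chr1", 2000, 2001, "+")], window_bp=1000, bin_bp=100)
    assert sps.chisquare(prof.counts).pvalue > 1e-3


# --- containment ------------------------------------------------------------


def test_containment_rule():
    pts = [iv("chr1", 90, 130)]
    count, pairs = containment_overlap(FeatureTrack("tfbs", [iv("chr1", 100, 120)]), pts)
    assert count == 1 and pairs[0][1].start == 90
    count, _ = containment_overlap(FeatureTrack("tfbs", [iv("chr1", 85, 95)]), pts)
    assert count == 0  # partial overlap does not count


def test_containment_matches_quadratic_oracle(rng):
    peaks = FeatureTrack("pk", random_intervals(rng, 400, max_len=40))
    pts = random_intervals(rng, 400, max_len=120)
    count, _ = containment_overlap(peaks, pts)
    expected = sum(
        1
        for q in peaks
        if any(p.chrom == q.chrom and p.start <= q.start and q.stop <= p.stop for p in pts)
    )
    assert count == expected


def test_containment_monotone_under_widening(rng):
    peaks = FeatureTrack("pk", random_intervals(rng, 200, max_len=50))
    pts = random_intervals(rng, 100, max_len=80)
    narrow, _ = containment_overlap(peaks, pts)
    widened = [iv(p.chrom, max(0, p.start - 30), p.stop + 30) for p in pts]
    wide, _ = containment_overlap(peaks, widened)
    assert wide >= narrow


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 80)), max_size=30))
def test_total_bases_equals_union(spans):
    track = FeatureTrack("u", [iv("chr1", s, s + w) for s, w in spans])
    covered = set()
    for s, w in spans:
        covered.update(range(s, s + w))
    assert track.total_bases == len(covered)
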