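import numpy as np
import pytest

from triplexome.features import FeatureTrack, GenomicInterval
from triplexome.search import SearchParams
from triplexome.simulate import SyntheticGenomeSpec, make_genome, write_fasta
from triplexome.stats import (
    ContingencyTable2x2,
    build_contingency,
    chisq_2x2,
    compare_gene_classes,
    enrichment_table,
    random_region_baseline,
)


def iv(chrom, start, stop, name=""):
    return GenomicInterval(chrom, start, stop, ".", name)


def test_chisq_closed_form():
    res = chisq_2x2(ContingencyTable2x2(10, 20, 30, 40))
    # N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 100 * 200^2 / 5.04e6
    assert res.chi_square == pytest.approx(100 * 200**2 / 5_040_000, abs=1e-12)
    assert res.df == 1 and 0 < res.p_value < 1


def test_chisq_independence_is_zero():
    res = chisq_2x2(ContingencyTable2x2(7, 7, 7, 7))
    assert res.chi_square == 0.0 and res.p_value == pytest.approx(1.0)
    assert res.direction == "none"


def test_degenerate_margin_is_fatal():
    with pytest.raises(ValueError, match="degenerate margin"):
        chisq_2x2(ContingencyTable2x2(0, 0, 5, 5))
    with pytest.raises(ValueError, match="degenerate margin"):
        chisq_2x2(ContingencyTable2x2(5, 0, 5, 0))


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 1, 1, 1)
    with pytest.raises(ValueError):
        ContingencyTable2x2(0, 0, 0, 0)


def test_chisq_invariances(rng):
    for _ in range(20):
        a, b, c, d = (int(x) for x in rng.integers(1, 200, 4))
        base = chisq_2x2(ContingencyTable2x2(a, b, c, d)).chi_square
        transpose = chisq_2x2(ContingencyTable2x2(a, c, b, d)).chi_square
        both_swapped = chisq_2x2(ContingencyTable2x2(d, c, b, a)).chi_square
        assert transpose == pytest.approx(base) and both_swapped == pytest.approx(base)


def test_p_monotone_in_statistic():
    tables = [(10, 10, 10, 10), (12, 8, 8, 12), (16, 4, 4, 16), (19, 1, 1, 19)]
    results = [chisq_2x2(ContingencyTable2x2(*t)) for t in tables]
    chis = [r.chi_square for r in results]
    ps = [r.p_value for r in results]
    assert chis == sorted(chis)
    assert ps == sorted(ps, reverse=True)


def test_direction_flips_with_complement():
    enr = chisq_2x2(ContingencyTable2x2(30, 10, 20, 40))
    dep = chisq_2x2(ContingencyTable2x2(10, 30, 40, 20))  # track complemented
    assert enr.direction == "enriched" and dep.direction == "depleted"
    assert enr.chi_square == pytest.approx(dep.chi_square)


def test_build_contingency_simple():
    t = build_contingency([iv("chr1", 0, 10)], FeatureTrack("tk", [iv("chr1", 0, 10)]), genome_size=100)
    assert (t.a, t.b, t.c, t.d) == (10, 0, 0, 90)
    t = build_contingency([iv("chr1", 0, 10)], FeatureTrack("tk", [iv("chr1", 50, 60)]), genome_size=100)
    assert t.a == 0 and t.b == 10 and t.c == 10 and t.d == 80


def test_build_contingency_matches_per_base_oracle(rng):
    genome_size = 5000
    for _ in range(10):
        pts = [iv("chr1", int(s), int(s) + int(w)) for s, w in zip(rng.integers(0, 4800, 40), rng.integers(1, 150, 40))]
        track_ivs = [iv("chr1", int(s), int(s) + int(w)) for s, w in zip(rng.integers(0, 4800, 15), rng.integers(1, 150, 15))]
        pts = [p for p in pts if p.stop <= genome_size]
        track_ivs = [p for p in track_ivs if p.stop <= genome_size]
        t = build_contingency(pts, FeatureTrack("tk", track_ivs), genome_size=genome_size)
        in_pts = np.zeros(genome_size, dtype=bool)
        in_tk = np.zeros(genome_size, dtype=bool)
        for p in pts:
            in_pts[p.start : p.stop] = True
        for q in track_ivs:
            in_tk[q.start : q.stop] = True
        assert (t.a, t.b, t.c, t.d) == (
            int((in_pts & in_tk).sum()),
            int((in_pts & ~in_tk).sum()),
            int((~in_pts & in_tk).sum()),
            int((~in_pts & ~in_tk).sum()),
        )


def test_region_unit_needs_background():
    track = FeatureTrack("tk", [iv("chr1", 0, 10)])
    with pytest.raises(ValueError, match="background"):
        build_contingency([iv("chr1", 0, 5)], track, unit="regions")
    bg = FeatureTrack("bg", [iv("chr1", 100, 120), iv("chr1", 200, 220)])
    t = build_contingency([iv("chr1", 0, 5)], track, unit="regions", background=bg)
    assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 2)


def test_baseline_zero_on_repeat_genome(tmp_path):
    path = tmp_path / "g.fa"
    write_fasta({"chr1": "AC" * 3000}, path)
    base = random_region_baseline(path, n_regions=50, region_length=500, seed=1)
    assert base.frequency_per_base == 0.0 and base.pts_count == 0


def test_baseline_counts_full_coverage_tract(tmp_path):
    path = tmp_path / "g.fa"
    write_fasta({"chr1": "A" * 5000}, path)
    base = random_region_baseline(path, n_regions=20, region_length=500, seed=1)
    # every region is one maximal window: one site per region
    assert base.frequency_per_base == pytest.approx(1 / 500)


def test_baseline_tracks_planted_density(tmp_path):
    """Baseline frequency is within 3 SE of the full-genome density."""
    params = SearchParams()
    genome = make_genome(SyntheticGenomeSpec(genome_length=60_000, n_tracts=12, seed=4), params)
    path = tmp_path / "g.fa"
    write_fasta(genome.sequences, path)
    from triplexome.search import find_tts_candidates

    chrom = next(iter(genome.sequences))
    full = len(find_tts_candidates(genome.sequences[chrom], chrom, params)) / len(genome.sequences[chrom])
    base = random_region_baseline(path, n_regions=400, region_length=1000, seed=7, params=params)
    assert abs(base.frequency_per_base - full) <= 3 * base.standard_error + 1e-12


def test_compare_gene_classes_directions():
    pts = [iv("chr1", 0, 1000)]
    klass_a = FeatureTrack("hk", [iv("chr1", 0, 500)])  # fully covered
    klass_b = FeatureTrack("ts", [iv("chr1", 5000, 5500)])  # untouched
    res = compare_gene_classes(pts, klass_a, klass_b)
    assert res.direction == "enriched" and res.p_value < 1e-10
    res_swapped = compare_gene_classes(pts, klass_b, klass_a)
    assert res_swapped.direction == "depleted"


def test_compare_identical_classes_is_null():
    pts = [iv("chr1", 0, 100)]
    track = FeatureTrack("hk", [iv("chr1", 0, 500)])
    res = compare_gene_classes(pts, track, FeatureTrack("ts", track.intervals))
    assert res.chi_square == 0.0


def test_planted_density_ratio_recovered(rng):
    """Promoters packed with twice the PTS density of introns give a
    fold estimate near 2."""
    promoters = FeatureTrack("prom", [iv("chr1", i * 2000, i * 2000 + 1000) for i in range(100)])
    introns = FeatureTrack("intr", [iv("chr2", i * 2000, i * 2000 + 1000) for i in range(100)])
    pts = []
    for i in range(100):  # 200 covered bases per promoter, 100 per intron
        pts.append(iv("chr1", i * 2000 + 100, i * 2000 + 300))
        pts.append(iv("chr2", i * 2000 + 100, i * 2000 + 200))
    res = compare_gene_classes(pts, promoters, introns)
    ratio = (res.table.a / (res.table.a + res.table.b)) / (res.table.c / (res.table.c + res.table.d))
    assert ratio == pytest.approx(2.0, rel=0.1)
    assert res.direction == "enriched" and res.p_value < 0.01


def test_enrichment_table_reports_q_values():
    pts = [iv("chr1", 0, 200)]
    tracks = [
        FeatureTrack("hit", [iv("chr1", 0, 300)]),
        FeatureTrack("miss", [iv("chr1", 5000, 5300)]),
        FeatureTrack("empty", []),
    ]
    frame = enrichment_table(pts, tracks, genome_size=10_000)
    assert list(frame.track_label) == ["hit", "miss", "empty"]
    ok = frame[frame.track_label == "hit"].iloc[0]
    assert ok.direction == "enriched" and ok.q_value <= 1
    assert frame[frame.track_label == "empty"].iloc[0].direction.startswith("undefined")
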