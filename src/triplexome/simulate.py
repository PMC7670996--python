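"""Synthetic inputs with known ground truth.

Everything the screen consumes can be generated here: a genome with
planted polypurine tracts, lncRNAs with planted triplex-forming
stretches, annotation tracks with controlled overlap, and expression
matrices with planted correlated pairs.  Two structural guarantees make
recovery tests exact rather than statistical:

* **Background-hit impossibility.**  Background sequence is i.i.d. with
  every purine/pyrimidine run (genome) and every motif-alphabet run
  (lncRNAs) capped at a length ``R`` chosen so that any window of
  length >= ``min_length`` must, by pigeonhole (at least
  ``floor(L / (R + 1))`` errors in any window of length ``L``), exceed
  the error budget.  At the default l = 35, e = 0.10 the derived cap is
  R = 7.  No background window can therefore be a candidate, and no hit
  can avoid overlapping planted sequence.

* **Exact planted-hit coordinates.**  Each planted TFO stretch carries
  exactly ``floor(e * L)`` error positions and off-alphabet immediate
  flanks, which makes the stretch a maximal window that cannot extend:
  one more base adds one more error and breaks the budget.  The TFO
  window is then never longer than its target tract's window, so the
  core-to-core alignment offset always exists and the planted hit is
  recovered at exactly the planted coordinates.  (Tract lengths
  congruent to 9 mod 10 are excluded at e = 0.10, where the
  one-base extension would sit exactly on the budget boundary.)

Planted tract/TFO error positions coincide in the alignment, so the
hit's error count equals the planted count on both sides.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureTrack, GenomicInterval
from .motifs import TFO_PARTNER, revcomp
from .search import RATE_EPS, SearchParams

#: off-alphabet character used for planted TFO errors and flanks, per motif
#: (never G, so planted errors do not disturb the guanine rate)
_TFO_ERROR_CHAR = {"R": "C", "Y": "A", "M": "C"}
_MOTIF_CYCLE = ("R", "Y", "M")
_CLASSES = {"purine": set("AG"), "pyrimidine": set("CT"),
            "R": set("AG"), "Y": set("CT"), "M": set("GT")}


def derive_background_cap(params: SearchParams, max_cap: int = 64) -> int:
    """Largest run cap R making background candidate windows impossible.

    R is safe when every window length L >= min_length forces more than
    ``max_error_rate * L`` errors, i.e. ``floor(L / (R + 1)) > e * L``.
    The check is exact for small L and asymptotic (1/(R+1) > e) beyond.
    """
    e = params.max_error_rate
    l = params.min_length
    best = 0
    for r in range(1, max_cap + 1):
        if 1.0 / (r + 1) <= e + RATE_EPS:
            break
        horizon = 4 * (r + 1) * max(1, math.ceil(1.0 / (1.0 / (r + 1) - e))) + l
        ok = all(L // (r + 1) > e * L + RATE_EPS for L in range(l, horizon + 1))
        if ok:
            best = r
    if best == 0:
        raise ValueError("no background run cap can preclude candidate windows at these params")
    return best


@dataclass(frozen=True)
class PlantedTract:
    """One planted polypurine tract (the future TTS) with its truth."""

    chrom: str
    start: int
    stop: int
    motif: str
    purine_strand: str
    error_offsets: tuple[int, ...]
    recoverable: bool  # length >= params.min_length

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class PlantedTFO:
    transcript_id: str
    start: int
    stop: int
    tract_index: int
    motif: str


@dataclass
class SyntheticGenomeSpec:
    genome_length: int = 100_000
    n_tracts: int = 20
    tract_length_range: tuple[int, int] = (30, 60)
    tract_g_fraction: float = 0.15
    chrom: str = "chrS1"
    seed: int = 0


@dataclass
class GenomeSim:
    sequences: dict[str, str]
    tracts: list[PlantedTract]
    params: SearchParams


@dataclass
class LncSim:
    sequences: dict[str, str]
    tfos: list[PlantedTFO]


def _error_offsets(length: int, n_errors: int) -> tuple[int, ...]:
    """Evenly spread interior error positions (keeps long error-free runs
    intact so every planted window contains an anchor run)."""
    if n_errors == 0:
        return ()
    return tuple(round((j + 1) * length / (n_errors + 1)) for j in range(n_errors))


def _tract_lengths(rng: np.random.Generator, spec: SyntheticGenomeSpec, params: SearchParams) -> list[int]:
    lo, hi = spec.tract_length_range
    lengths = []
    while len(lengths) < spec.n_tracts:
        length = int(rng.integers(lo, hi + 1))
        n_err = int(params.max_error_rate * length + RATE_EPS)
        # exclude lengths where a one-base extension of the planted TFO
        # would sit exactly on the error budget (it must break it)
        if length >= params.min_length and n_err + 1 <= params.max_error_rate * (length + 1) + RATE_EPS:
            continue
        lengths.append(length)
    return lengths


def _iid_background(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n).astype(np.uint8)  # 0..3 = A,C,G,T


_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {c: i for i, c in enumerate("ACGT")}


def _cap_class_runs(
    codes: np.ndarray,
    classes: list[set[str]],
    cap: int,
    rng: np.random.Generator,
    frozen: np.ndarray,
) -> None:
    """Break every over-cap run of any character class in place.

    Positions marked frozen (planted) are never modified; an over-cap run
    with no free position is left alone (it is planted signal).
    """
    class_codes = [np.array(sorted(_CODE[c] for c in cls)) for cls in classes]
    complements = [np.array(sorted(set(range(4)) - {_CODE[c] for c in cls})) for cls in classes]
    for _ in range(200):
        changed = False
        for members, other in zip(class_codes, complements):
            mask = np.isin(codes, members)
            padded = np.concatenate(([False], mask, [False]))
            diff = np.diff(padded.astype(np.int8))
            starts = np.flatnonzero(diff == 1)
            stops = np.flatnonzero(diff == -1)
            for s, e in zip(starts, stops):
                if e - s <= cap:
                    continue
                free = np.flatnonzero(~frozen[s:e]) + s
                if free.size == 0:
                    continue
                # break the run near its middle where possible
                pos = free[np.argmin(np.abs(free - (s + e) // 2))]
                codes[pos] = rng.choice(other)
                changed = True
        if not changed:
            return
    raise RuntimeError("run capping did not converge")


def make_genome(spec: SyntheticGenomeSpec, params: SearchParams | None = None) -> GenomeSim:
    """Genome FASTA content plus the truth list of planted tracts.

    Tracts are non-overlapping, separated by at least 200 bases of
    run-capped background, alternate between + and - purine strands and
    cycle through the three motifs.  Each recoverable tract carries
    ``floor(e * L)`` planted pyrimidine errors on the purine strand.
    """
    params = params or SearchParams()
    rng = np.random.default_rng(spec.seed)
    cap = derive_background_cap(params)
    codes = _iid_background(rng, spec.genome_length)
    frozen = np.zeros(spec.genome_length, dtype=bool)

    lengths = _tract_lengths(rng, spec, params)
    gap = 200
    needed = sum(lengths) + gap * (len(lengths) + 1)
    if needed > spec.genome_length:
        raise ValueError("genome too short for the requested tracts")
    # place tracts at sorted random positions with the minimum gap
    slack = spec.genome_length - needed
    cuts = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
    tracts: list[PlantedTract] = []
    for i, length in enumerate(lengths):
        start = int(cuts[i]) + gap * (i + 1) + sum(lengths[:i])
        stop = start + length
        motif = _MOTIF_CYCLE[i % 3]
        strand = "+" if i % 2 == 0 else "-"
        recoverable = length >= params.min_length
        n_err = int(params.max_error_rate * length + RATE_EPS) if recoverable else 0
        offsets = _error_offsets(length, n_err)
        # exact G count: the partner TFO's guanine rate must respect the
        # guanine bound deterministically, not just in expectation
        g_count = int(round(spec.tract_g_fraction * length))
        if params.guanine_rate_bound is not None and params.guanine_bound_direction == "at_most":
            g_count = min(g_count, int(params.guanine_rate_bound * length + RATE_EPS))
        purine_seq = np.full(length, _CODE["A"], dtype=np.uint8)
        open_pos = np.array([p for p in range(length) if p not in offsets])
        for p in rng.choice(open_pos, size=min(g_count, open_pos.size), replace=False):
            purine_seq[p] = _CODE["G"]
        for off in offsets:
            purine_seq[off] = _CODE["C"]  # pyrimidine on the purine strand
        if strand == "+":
            codes[start:stop] = purine_seq
        else:
            # + strand carries the complement, reversed
            comp = np.array([3, 2, 1, 0], dtype=np.uint8)[purine_seq]
            codes[start:stop] = comp[::-1]
        frozen[start:stop] = True
        plus_offsets = offsets if strand == "+" else tuple(sorted(length - 1 - o for o in offsets))
        tracts.append(PlantedTract(spec.chrom, start, stop, motif, strand, plus_offsets, recoverable))
    _cap_class_runs(codes, [_CLASSES["purine"], _CLASSES["pyrimidine"]], cap, rng, frozen)
    seq = bytes(_ALPHABET[codes]).decode("ascii")
    return GenomeSim({spec.chrom: seq}, tracts, params)


def _purine_strand_seq(genome: GenomeSim, tract: PlantedTract) -> str:
    plus = genome.sequences[tract.chrom][tract.start : tract.stop]
    return plus if tract.purine_strand == "+" else revcomp(plus)


def make_lncrnas(
    genome: GenomeSim,
    n_lncrnas: int = 50,
    length_range: tuple[int, int] = (500, 1500),
    seed: int = 1,
) -> LncSim:
    """Transcripts with planted TFO stretches paired to planted tracts.

    Tract ``i`` is partnered with transcript ``i`` (decoy transcripts
    carry no planted stretch).  The planted stretch is the motif-code
    partner of the tract's purine-strand sequence read 5'->3' in the
    parallel frame — reversed for antiparallel motifs — with the
    motif-specific off-alphabet character at the planted error
    positions and on both immediate flanks.
    """
    params = genome.params
    rng = np.random.default_rng(seed)
    cap = derive_background_cap(params)
    n_lncrnas = max(n_lncrnas, len(genome.tracts))
    sequences: dict[str, str] = {}
    tfos: list[PlantedTFO] = []
    for i in range(n_lncrnas):
        tid = f"LNC{i + 1:04d}"
        length = int(rng.integers(*length_range))
        codes = _iid_background(rng, length)
        frozen = np.zeros(length, dtype=bool)
        if i < len(genome.tracts):
            tract = genome.tracts[i]
            purine = _purine_strand_seq(genome, tract)
            err_char = _TFO_ERROR_CHAR[tract.motif]
            partner = TFO_PARTNER[tract.motif]
            # parallel frame partner; at planted tract errors the purine
            # strand carries a pyrimidine -> plant the TFO error character
            tfo = "".join(partner.get(b, err_char) for b in purine)
            if tract.motif in ("R",):  # antiparallel-only motif: reverse
                tfo = tfo[::-1]
            core = np.frombuffer(tfo.encode(), dtype=np.uint8)
            core_codes = np.array([_CODE[chr(c)] for c in core], dtype=np.uint8)
            start = int(rng.integers(2, length - len(tfo) - 2))
            codes[start : start + len(tfo)] = core_codes
            codes[start - 1] = _CODE[err_char]
            codes[start + len(tfo)] = _CODE[err_char]
            frozen[start - 1 : start + len(tfo) + 1] = True
            tfos.append(PlantedTFO(tid, start, start + len(tfo), i, tract.motif))
        _cap_class_runs(codes, [_CLASSES["R"], _CLASSES["Y"], _CLASSES["M"]], cap, rng, frozen)
        sequences[tid] = bytes(_ALPHABET[codes]).decode("ascii")
    return LncSim(sequences, tfos)


def make_tracks(
    genome: GenomeSim,
    overlap_fractions: dict[str, float],
    seed: int = 2,
    pad: int = 20,
    n_background_intervals: int = 30,
    background_interval_length: int = 400,
) -> dict[str, FeatureTrack]:
    """Annotation tracks with a controlled fraction of tracts contained.

    For each label, ``round(fraction * n_tracts)`` planted tracts are
    chosen (without replacement) and wrapped in an interval with ``pad``
    bases of margin; the remaining intervals are placed in background,
    never touching any planted tract.
    """
    rng = np.random.default_rng(seed)
    chrom = genome.tracts[0].chrom if genome.tracts else next(iter(genome.sequences))
    n = len(genome.tracts)
    glen = len(genome.sequences[chrom])
    blocked = [(t.start - pad, t.stop + pad) for t in genome.tracts]
    tracks: dict[str, FeatureTrack] = {}
    for label, fraction in overlap_fractions.items():
        k = int(round(fraction * n))
        chosen = sorted(rng.choice(n, size=k, replace=False)) if k else []
        intervals = [
            GenomicInterval(chrom, genome.tracts[j].start - pad, genome.tracts[j].stop + pad, ".", f"{label}_{j}")
            for j in chosen
        ]
        placed = 0
        attempts = 0
        while placed < n_background_intervals - k and attempts < 10_000:
            attempts += 1
            s = int(rng.integers(0, glen - background_interval_length))
            e = s + background_interval_length
            if any(s < be and bs < e for bs, be in blocked):
                continue
            intervals.append(GenomicInterval(chrom, s, e, ".", f"{label}_bg{placed}"))
            placed += 1
        tracks[label] = FeatureTrack(label, sorted(intervals, key=lambda iv: (iv.start, iv.stop)))
    return tracks


@dataclass
class SyntheticExpressionSpec:
    n_lncrnas: int = 50
    n_genes: int = 100
    n_samples: int = 100
    planted: list[tuple[str, str, float]] = field(default_factory=list)
    log_sd: float = 0.5
    seed: int = 3


@dataclass
class ExpressionSim:
    lnc: pd.DataFrame
    genes: pd.DataFrame
    planted: list[tuple[str, str, float]]


def _calibrated_log_rho(rho: float, sigma: float) -> float:
    """Log-scale correlation whose exponentiated (FPKM-scale) Pearson
    correlation equals ``rho`` in expectation (lognormal identity)."""
    if rho == 0.0:
        return 0.0
    v = math.expm1(sigma**2)
    return math.log1p(rho * v) / sigma**2


def make_expression(spec: SyntheticExpressionSpec) -> ExpressionSim:
    """FPKM-scale expression matrices with planted correlated pairs.

    Profiles are lognormal: standard-normal log-abundances scaled by
    ``log_sd`` around a per-feature baseline drawn in [0, 3] (natural
    log), then exponentiated.  Planted pairs share a latent factor whose
    log-scale correlation is calibrated so the FPKM-scale Pearson r
    targets the requested rho; all other profiles are independent.
    """
    rng = np.random.default_rng(spec.seed)
    lnc_ids = [f"LNC{i + 1:04d}" for i in range(spec.n_lncrnas)]
    gene_ids = [f"GENE{i + 1:04d}" for i in range(spec.n_genes)]
    samples = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    z_lnc = rng.standard_normal((spec.n_lncrnas, spec.n_samples))
    z_gene = rng.standard_normal((spec.n_genes, spec.n_samples))
    lnc_index = {t: i for i, t in enumerate(lnc_ids)}
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for lnc, gene, rho in spec.planted:
        if lnc not in lnc_index or gene not in gene_index:
            raise ValueError(f"planted pair ({lnc}, {gene}) outside the matrix ids")
        r = _calibrated_log_rho(rho, spec.log_sd)
        shared = z_lnc[lnc_index[lnc]]
        z_gene[gene_index[gene]] = r * shared + math.sqrt(1 - r**2) * rng.standard_normal(spec.n_samples)
    mu_lnc = rng.uniform(0, 3, size=spec.n_lncrnas)[:, None]
    mu_gene = rng.uniform(0, 3, size=spec.n_genes)[:, None]
    lnc = pd.DataFrame(np.exp(mu_lnc + spec.log_sd * z_lnc), index=lnc_ids, columns=samples)
    genes = pd.DataFrame(np.exp(mu_gene + spec.log_sd * z_gene), index=gene_ids, columns=samples)
    return ExpressionSim(lnc, genes, list(spec.planted))


# ---------------------------------------------------------------------------
# file emission and scan evaluation


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def evaluate_scan(hits, genome: GenomeSim, lnc: LncSim) -> dict[str, float]:
    """Positional recall/precision of a hit list against planted truth.

    * ``pair_recall``: fraction of recoverable planted pairs for which
      some hit joins the partner transcript to an interval overlapping
      its tract.
    * ``site_precision``: fraction of hits whose TTS overlaps a planted
      tract and whose TFO overlaps a planted TFO stretch of the same
      transcript (run-capped background makes anything else a false
      positive).
    """
    tract_by_index = {i: t for i, t in enumerate(genome.tracts)}
    tfo_by_tid: dict[str, list[PlantedTFO]] = {}
    for p in lnc.tfos:
        tfo_by_tid.setdefault(p.transcript_id, []).append(p)
    recoverable = [p for p in lnc.tfos if tract_by_index[p.tract_index].recoverable]
    recovered = 0
    for planted in recoverable:
        tract = tract_by_index[planted.tract_index]
        if any(
            h.transcript_id == planted.transcript_id
            and h.chrom == tract.chrom
            and h.tts_start < tract.stop
            and tract.start < h.tts_stop
            for h in hits
        ):
            recovered += 1
    true_hits = 0
    for h in hits:
        tts_ok = any(
            h.chrom == t.chrom and h.tts_start < t.stop and t.start < h.tts_stop for t in genome.tracts
        )
        tfo_ok = any(
            h.tfo_start < p.stop and p.start < h.tfo_stop for p in tfo_by_tid.get(h.transcript_id, ())
        )
        if tts_ok and tfo_ok:
            true_hits += 1
    return {
        "pair_recall": recovered / len(recoverable) if recoverable else float("nan"),
        "site_precision": true_hits / len(hits) if hits else float("nan"),
        "n_hits": float(len(hits)),
        "n_recoverable_pairs": float(len(recoverable)),
    }


def write_truth_manifest(genome: GenomeSim, lnc: LncSim, path: str | Path) -> None:
    manifest = {
        "tracts": [asdict(t) for t in genome.tracts],
        "tfos": [asdict(p) for p in lnc.tfos],
        "params": asdict(genome.params),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def simulate_preset(
    out_dir: str | Path,
    seed: int = 0,
    genome_spec: SyntheticGenomeSpec | None = None,
    params: SearchParams | None = None,
    n_lncrnas: int = 50,
    expression_rho: float = 0.9,
) -> dict:
    """Write the default synthetic study to ``out_dir``.

    One 100-kb chromosome with 20 planted tracts, 50 lncRNAs (20 with
    planted TFOs), promoter/intron/CpG tracks (promoters contain every
    tract; introns half; CpG none), chromosome sizes, and expression
    matrices in which each planted triplex pair is also a planted
    co-expression pair at the requested rho.  Returns the path map plus
    the in-memory truth objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or SearchParams()
    spec = genome_spec or SyntheticGenomeSpec(seed=seed)
    genome = make_genome(spec, params)
    lnc = make_lncrnas(genome, n_lncrnas=n_lncrnas, seed=seed + 1)
    tracks = make_tracks(
        genome, {"promoter": 1.0, "intron": 0.5, "cpg_island": 0.0}, seed=seed + 2
    )
    # promoter intervals carry the partner gene ids for the network stage
    promoter = tracks["promoter"]
    gene_names = {}
    renamed = []
    for iv in promoter.intervals:
        if iv.name.startswith("promoter_bg"):
            renamed.append(iv)
            continue
        idx = int(iv.name.split("_")[1])
        gene = f"GENE{idx + 1:04d}"
        gene_names[idx] = gene
        renamed.append(GenomicInterval(iv.chrom, iv.start, iv.stop, iv.strand, gene))
    tracks["promoter"] = FeatureTrack("promoter", renamed)
    planted_pairs = [
        (p.transcript_id, gene_names[p.tract_index], expression_rho)
        for p in lnc.tfos
        if p.tract_index in gene_names and genome.tracts[p.tract_index].recoverable
    ]
    expr = make_expression(
        SyntheticExpressionSpec(n_lncrnas=max(n_lncrnas, 50), planted=planted_pairs, seed=seed + 3)
    )
    paths = {
        "genome_fasta": str(out / "genome.fa"),
        "lncrna_fasta": str(out / "lncrnas.fa"),
        "chrom_sizes": str(out / "chrom.sizes"),
        "truth_manifest": str(out / "truth.json"),
        "lnc_expression": str(out / "lnc_expression.tsv"),
        "gene_expression": str(out / "gene_expression.tsv"),
        "tracks": {},
    }
    write_fasta(genome.sequences, paths["genome_fasta"])
    write_fasta(lnc.sequences, paths["lncrna_fasta"])
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, seq in genome.sequences.items():
            fh.write(f"{chrom}\t{len(seq)}\n")
    from .features import write_bed

    for label, track in tracks.items():
        p = str(out / f"track_{label}.bed")
        write_bed(track, p)
        paths["tracks"][label] = p
    expr.lnc.to_csv(paths["lnc_expression"], sep="\t")
    expr.genes.to_csv(paths["gene_expression"], sep="\t")
    write_truth_manifest(genome, lnc, paths["truth_manifest"])
    return {
        "paths": paths,
        "genome": genome,
        "lncrnas": lnc,
        "tracks": tracks,
        "expression": expr,
        "planted_pairs": planted_pairs,
    }
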