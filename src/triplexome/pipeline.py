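"""End-to-end orchestration: scan -> annotate -> enrich -> network.

Every stage writes plain files under stable names in the output
directory, so any stage can be re-run standalone from the previous
stage's outputs.  A manifest records the full configuration, SHA-256
digests of all inputs, and per-stage counts; a re-run from the same
configuration is byte-identical (no timestamps enter any output).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .features import FeatureTrack, chromosome_frequency, count_in_features, hits_to_intervals, metagene_profile, read_bed
from .match import scan_motifs, write_hits_tsv, write_tts_bed
from .network import build_network, candidate_pairs, edges_to_frame, export_network, read_expression
from .search import SearchParams
from .stats import enrichment_table, random_region_baseline

logger = logging.getLogger(__name__)

STAGES = ("scan", "annotate", "enrich", "network")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    lncrna_fasta: str
    genome_fasta: str
    out_dir: str
    tracks: dict[str, str] = field(default_factory=dict)  # label -> BED path
    chrom_sizes: str | None = None
    anchors_bed: str | None = None
    lnc_expression: str | None = None
    gene_expression: str | None = None
    promoter_label: str = "promoter"
    motifs: tuple[str, ...] = ("R", "Y", "M")
    min_length: int = 35
    max_error_rate: float = 0.10
    guanine_rate_bound: float | None = 0.20
    guanine_bound_direction: str = "at_most"
    max_consecutive_errors: int | None = None
    r_threshold: float = 0.80
    p_threshold: float = 0.01
    baseline_regions: int = 0  # 0 disables the random-region baseline
    baseline_region_length: int = 1000
    metagene_window: int = 2000
    metagene_bin: int = 100
    seed: int = 0
    threads: int = 1  # accepted for interface parity; results are thread-count independent

    @property
    def params(self) -> SearchParams:
        return SearchParams(
            min_length=self.min_length,
            max_error_rate=self.max_error_rate,
            guanine_rate_bound=self.guanine_rate_bound,
            guanine_bound_direction=self.guanine_bound_direction,
            max_consecutive_errors=self.max_consecutive_errors,
        )

    def validate(self) -> None:
        _ = self.params  # raises on invalid search parameters
        for label, path in [("lncrna_fasta", self.lncrna_fasta), ("genome_fasta", self.genome_fasta)]:
            if not Path(path).exists():
                raise FileNotFoundError(f"{label} input missing: {path}")
        for lbl, path in self.tracks.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"track {lbl!r} input missing: {path}")
        for lbl in ("chrom_sizes", "anchors_bed", "lnc_expression", "gene_expression"):
            path = getattr(self, lbl)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{lbl} input missing: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "motifs" in raw:
            raw["motifs"] = tuple(raw["motifs"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["motifs"] = list(self.motifs)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dictionary.

    A stage failure raises :class:`StageError` naming the stage.  The
    manifest (``manifest.json``) and log (``pipeline.log``) are written
    in the output directory alongside the stage outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("triplexome")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    counts: dict[str, int | float] = {}
    try:
        # --- scan ---------------------------------------------------
        try:
            hits = scan_motifs(config.lncrna_fasta, config.genome_fasta, config.params, config.motifs)
            write_hits_tsv(hits, out / "hits.tsv", lncrna_fasta=config.lncrna_fasta)
            write_tts_bed(hits, out / "tts.bed")
            counts["hits"] = len(hits)
            counts["triplex_lncrnas"] = len({h.transcript_id for h in hits})
            logger.info("scan: %d hits from %d transcripts", len(hits), counts["triplex_lncrnas"])
        except Exception as exc:
            raise StageError(f"stage scan failed: {exc}") from exc

        pts = hits_to_intervals(hits)
        tracks = {label: read_bed(path, label=label) for label, path in config.tracks.items()}

        # --- annotate -----------------------------------------------
        try:
            if tracks:
                freq = count_in_features(pts, list(tracks.values()))
                freq.to_csv(out / "feature_frequency.tsv", sep="\t", index=False)
                counts["feature_rows"] = len(freq)
            if config.chrom_sizes:
                sizes = _read_chrom_sizes(config.chrom_sizes)
                chromosome_frequency(pts, sizes).to_csv(out / "chromosome_frequency.tsv", sep="\t", index=False)
            if config.anchors_bed:
                anchors = read_bed(config.anchors_bed).intervals
                profile = metagene_profile(pts, anchors, config.metagene_window, config.metagene_bin)
                profile.to_frame().to_csv(out / "metagene_tss.tsv", sep="\t", index=False)
        except Exception as exc:
            raise StageError(f"stage annotate failed: {exc}") from exc

        # --- enrich -------------------------------------------------
        try:
            if tracks and config.chrom_sizes:
                sizes = _read_chrom_sizes(config.chrom_sizes)
                genome_size = sum(sizes.values())
                enrich = enrichment_table(pts, list(tracks.values()), genome_size)
                enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                counts["enrichment_rows"] = len(enrich)
            if config.baseline_regions:
                baseline = random_region_baseline(
                    config.genome_fasta,
                    n_regions=config.baseline_regions,
                    region_length=config.baseline_region_length,
                    seed=config.seed,
                    params=config.params,
                )
                (out / "random_baseline.json").write_text(json.dumps(asdict(baseline), indent=1, sort_keys=True))
                counts["baseline_frequency_per_base"] = baseline.frequency_per_base
        except Exception as exc:
            raise StageError(f"stage enrich failed: {exc}") from exc

        # --- network ------------------------------------------------
        try:
            if config.lnc_expression and config.gene_expression and config.promoter_label in tracks:
                pairs = candidate_pairs(hits, tracks[config.promoter_label])
                lnc_expr = read_expression(config.lnc_expression)
                gene_expr = read_expression(config.gene_expression)
                edges, nodes = build_network(
                    pairs, lnc_expr, gene_expr, config.r_threshold, config.p_threshold
                )
                edges_to_frame(edges).to_csv(out / "network_edges.tsv", sep="\t", index=False)
                nodes.to_csv(out / "network_nodes.tsv", sep="\t", index=False)
                export_network(edges, out / "network.sif", format="SIF")
                export_network(edges, out / "network.graphml", format="GraphML")
                counts["candidate_pairs"] = len(pairs)
                counts["network_edges"] = len(edges)
                logger.info("network: %d edges from %d candidate pairs", len(edges), len(pairs))
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage network failed: {exc}") from exc

        digests = {"lncrna_fasta": _sha256(config.lncrna_fasta), "genome_fasta": _sha256(config.genome_fasta)}
        for lbl, path in config.tracks.items():
            digests[f"track:{lbl}"] = _sha256(path)
        for lbl in ("chrom_sizes", "anchors_bed", "lnc_expression", "gene_expression"):
            path = getattr(config, lbl)
            if path:
                digests[lbl] = _sha256(path)
        cfg = asdict(config)
        cfg["motifs"] = list(config.motifs)
        manifest = {"config": cfg, "input_digests": digests, "counts": counts}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        config.to_yaml(out / "config.yaml")
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
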