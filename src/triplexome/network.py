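"""lncRNA-target co-expression network from triplex predictions.

Candidate pairs are (lncRNA, gene) combinations where some predicted
TTS of the lncRNA overlaps the gene's promoter interval.  For each
pair the Pearson correlation of the two expression profiles (FPKM
scale) is computed with a two-sided p-value from the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` on n - 2 degrees of freedom.
Edges with ``r > +threshold`` (positive regulation) or
``r < -threshold`` (negative), both with ``p < p_threshold``, form the
network, exportable as SIF, TSV and GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureTrack, _as_intervals
from .io import normalize_chrom

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """Raised when a profile has zero variance (r is undefined)."""


@dataclass(frozen=True)
class CorrelationEdge:
    lncrna_id: str
    gene_id: str
    r: float
    p_value: float

    @property
    def sign(self) -> str:
        return "positive" if self.r > 0 else "negative"


def read_expression(path: str | Path, log_transform: bool = False) -> pd.DataFrame:
    """Read a TSV expression matrix (rows = features, columns = samples).

    Values are FPKM-scale non-negative reals used as-is by default;
    ``log_transform`` applies log2(x + 1).  Duplicate row ids and rows
    with fewer than 3 finite values are hard errors.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate expression row id {dup!r} in {path}")
    finite = np.isfinite(frame.to_numpy(dtype=float)).sum(axis=1)
    if (finite < 3).any():
        bad = frame.index[finite < 3][0]
        raise ValueError(f"expression row {bad!r} has fewer than 3 finite values")
    if log_transform:
        frame = np.log2(frame + 1.0)
    return frame


def candidate_pairs(hits, promoter_track: FeatureTrack) -> list[tuple[str, str]]:
    """(lncRNA, gene) pairs whose TTS overlaps the gene's promoter.

    Promoter intervals must carry the gene id in their ``name`` field.
    Each pair is emitted once, in sorted order.
    """
    intervals = _as_intervals(hits)
    pairs: set[tuple[str, str]] = set()
    trees = promoter_track.trees
    for iv in intervals:
        lnc = iv.name.split(":")[0] if iv.name else ""
        chrom = normalize_chrom(iv.chrom)
        if chrom not in trees:
            continue
        for match in trees[chrom].overlap(iv.start, iv.stop):
            gene = match.data.name
            if lnc and gene:
                pairs.add((lnc, gene))
    return sorted(pairs)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p (t transform, n - 2 df).

    Vectors must be equal length with n >= 3; zero-variance input
    raises :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero-variance vector: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_network(
    pairs: list[tuple[str, str]],
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    r_threshold: float = 0.80,
    p_threshold: float = 0.01,
) -> tuple[list[CorrelationEdge], pd.DataFrame]:
    """Threshold candidate pairs into network edges.

    Pairs absent from either matrix, or with zero-variance profiles,
    are skipped and logged.  Returns the surviving edges and a node
    table (id, type, degree).
    """
    common = [c for c in lnc_expr.columns if c in set(gene_expr.columns)]
    if len(common) < 3:
        raise ValueError("expression matrices share fewer than 3 samples")
    edges: list[CorrelationEdge] = []
    for lnc, gene in pairs:
        if lnc not in lnc_expr.index or gene not in gene_expr.index:
            logger.info("pair (%s, %s) missing from expression data; skipped", lnc, gene)
            continue
        try:
            r, p = pearson_with_p(lnc_expr.loc[lnc, common], gene_expr.loc[gene, common])
        except UndefinedCorrelationError:
            logger.info("pair (%s, %s) has a zero-variance profile; skipped", lnc, gene)
            continue
        if abs(r) > r_threshold and p < p_threshold:
            edges.append(CorrelationEdge(lnc, gene, r, p))
    degree: dict[tuple[str, str], int] = {}
    for e in edges:
        degree[(e.lncrna_id, "lncRNA")] = degree.get((e.lncrna_id, "lncRNA"), 0) + 1
        degree[(e.gene_id, "gene")] = degree.get((e.gene_id, "gene"), 0) + 1
    nodes = pd.DataFrame(
        [{"id": nid, "type": ntype, "degree": deg} for (nid, ntype), deg in sorted(degree.items())],
        columns=["id", "type", "degree"],
    )
    return edges, nodes


def edges_to_frame(edges: list[CorrelationEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"lncrna_id": e.lncrna_id, "gene_id": e.gene_id, "r": e.r, "p_value": e.p_value, "sign": e.sign}
            for e in edges
        ],
        columns=["lncrna_id", "gene_id", "r", "p_value", "sign"],
    )


def frame_to_edges(frame: pd.DataFrame) -> list[CorrelationEdge]:
    return [
        CorrelationEdge(row.lncrna_id, row.gene_id, float(row.r), float(row.p_value))
        for row in frame.itertuples()
    ]


def export_network(edges: list[CorrelationEdge], path: str | Path, format: str = "TSV") -> None:
    """Write the edge set as SIF, TSV or GraphML.

    SIF lines read ``lnc positively_correlates gene`` (or
    ``negatively_correlates``); TSV round-trips losslessly through
    :func:`frame_to_edges`; GraphML carries r and p as edge attributes.
    """
    fmt = format.upper()
    if fmt == "SIF":
        with open(path, "w") as fh:
            for e in edges:
                rel = "positively_correlates" if e.sign == "positive" else "negatively_correlates"
                fh.write(f"{e.lncrna_id}\t{rel}\t{e.gene_id}\n")
    elif fmt == "TSV":
        edges_to_frame(edges).to_csv(path, sep="\t", index=False)
    elif fmt == "GRAPHML":
        g = nx.Graph()
        for e in edges:
            g.add_node(e.lncrna_id, node_type="lncRNA")
            g.add_node(e.gene_id, node_type="gene")
            g.add_edge(e.lncrna_id, e.gene_id, r=e.r, p_value=e.p_value, sign=e.sign)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")
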