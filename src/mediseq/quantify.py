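"""Per-gene positional coverage and median-of-coverage expression.

A gene's track is the concatenation of its quantified features in
transcript coordinates (exon union by default; miRNA rows are their own
track). Every assigned read increments depth by its per-sample
occurrence count at each track position it covers, and a gene's
expression in a sample is the median depth over *all* track positions,
zeros included — the median is what makes the estimate robust to spiky
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import Assignment
from .features import FeatureModel

RAW = "raw"
QUANTILE = "quantile"


@dataclass
class CoverageTrack:
    gene_id: str
    sample_id: str
    depth: np.ndarray  # transcript-coordinate depths, length == track length

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be 1-D")
        if (self.depth < 0).any():
            raise ValueError("negative depth")


def median_expression(depth: np.ndarray) -> float:
    """Median depth over the whole track, zeros included; the even-length
    median is the mean of the central pair."""
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("zero-length coverage track")
    return float(np.median(depth))


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a normalization state."""

    values: pd.DataFrame
    normalization_state: str = RAW

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.normalization_state not in (RAW, QUANTILE):
            raise ValueError(f"unknown state {self.normalization_state!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, normalization_state: str = RAW) -> "ExpressionMatrix":
        return cls(
            pd.read_csv(path, sep="\t", index_col="gene_id"), normalization_state
        )


class _TrackLayout:
    """Maps assigned features into one concatenated transcript-coordinate
    space (one slab per gene) so coverage can be built with bincounts."""

    def __init__(self, assignment: Assignment, model: FeatureModel, span: str):
        tracks = model.gene_tracks(span=span)
        self.genes = list(tracks)
        self.slab_offset = {}
        self.track_length = {}
        feature_gene: dict[str, tuple[int, int, int, int]] = {}
        total = 0
        for gi, gene in enumerate(self.genes):
            self.slab_offset[gene] = total
            off = 0
            for f in tracks[gene]:
                feature_gene[f.feature_id] = (gi, total + off, f.start, f.end)
                off += f.length
            self.track_length[gene] = off
            total += off
        self.total_length = total
        self._feature_gene = feature_gene

        # per assigned feature index: slab position of its start, or -1
        n_feat = len(assignment.features)
        self.feat_slab = np.full(n_feat, -1, dtype=np.int64)
        self.feat_start = np.zeros(n_feat, dtype=np.int64)
        self.feat_end = np.zeros(n_feat, dtype=np.int64)
        for j, f in enumerate(assignment.features):
            rec = feature_gene.get(f.feature_id)
            if rec is not None:
                _, slab, fstart, fend = rec
                self.feat_slab[j] = slab
                self.feat_start[j] = fstart
                self.feat_end[j] = fend


def coverage_matrix(
    assignment: Assignment,
    model: FeatureModel,
    span: str = "exon",
    on_escape: str = "error",
) -> tuple[ExpressionMatrix, dict[str, np.ndarray]]:
    """Build all coverage tracks and the raw median-expression matrix.

    Returns the matrix plus a dict of per-gene depth arrays stacked over
    samples (shape ``track_length x n_samples``). Reads assigned to
    features outside the chosen track span (e.g. introns with
    ``span='exon'``, intergenic) contribute nothing. A read extending
    beyond its assigned feature raises unless ``on_escape='clip'``.
    """
    if on_escape not in ("error", "clip"):
        raise ValueError("on_escape must be 'error' or 'clip'")
    layout = _TrackLayout(assignment, model, span)
    samples = assignment.table.samples
    rl = assignment.read_length

    fj = assignment.feature_idx
    in_track = layout.feat_slab[fj] >= 0
    s = assignment.start[in_track]
    e = s + rl
    fj = fj[in_track]
    rows = assignment.read_idx[in_track]

    fstart = layout.feat_start[fj]
    fend = layout.feat_end[fj]
    if on_escape == "error":
        bad = np.flatnonzero((s < fstart) | (e > fend))
        if bad.size:
            b = int(bad[0])
            raise ValueError(
                f"read [{int(s[b])}, {int(e[b])}) escapes its assigned feature "
                f"[{int(fstart[b])}, {int(fend[b])})"
            )
    cs = np.clip(s, fstart, fend)
    ce = np.clip(e, fstart, fend)
    pos_start = layout.feat_slab[fj] + (cs - fstart)
    pos_end = layout.feat_slab[fj] + (ce - fstart)

    total = layout.total_length
    depth = np.zeros((total, len(samples)))
    counts = assignment.table.counts
    for j in range(len(samples)):
        w = counts[rows, j].astype(float)
        d = np.bincount(pos_start, weights=w, minlength=total + 1)
        d -= np.bincount(pos_end, weights=w, minlength=total + 1)
        depth[:, j] = np.cumsum(d)[:total]

    med = np.empty((len(layout.genes), len(samples)))
    tracks_out: dict[str, np.ndarray] = {}
    for gi, gene in enumerate(layout.genes):
        a = layout.slab_offset[gene]
        b = a + layout.track_length[gene]
        slab = depth[a:b]
        tracks_out[gene] = slab
        med[gi] = np.median(slab, axis=0) if slab.size else 0.0

    matrix = ExpressionMatrix(
        pd.DataFrame(med, index=pd.Index(layout.genes, name="gene_id"),
                     columns=samples),
        RAW,
    )
    return matrix, tracks_out


def build_coverage(
    assignment: Assignment,
    model: FeatureModel,
    sample: str,
    span: str = "exon",
    on_escape: str = "error",
) -> list[CoverageTrack]:
    """Coverage tracks for one sample (transcript coordinates)."""
    if sample not in assignment.table.samples:
        raise KeyError(f"unknown sample {sample!r}")
    j = assignment.table.samples.index(sample)
    _, tracks = coverage_matrix(assignment, model, span=span, on_escape=on_escape)
    return [
        CoverageTrack(gene, sample, depth[:, j]) for gene, depth in tracks.items()
    ]


def write_bedgraph(tracks: list[CoverageTrack], path) -> None:
    """Per-gene transcript-coordinate coverage in bedGraph layout."""
    with open(path, "w") as fh:
        for t in tracks:
            d = t.depth
            i = 0
            while i < d.size:
                j = i
                while j < d.size and d[j] == d[i]:
                    j += 1
                fh.write(f"{t.gene_id}\t{i}\t{j}\t{d[i]:g}\n")
                i = j
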