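"""Exact-match placement of unique reads on the toy genome and
hierarchy-based feature identity assignment.

Placement is exact substring lookup against a k-mer index of the
forward strand (the toy genome is forward-only). Reads with zero or
multiple genomic occurrences are not errors; they are routed to an
``unplaced`` tally with a reason. Each placed read then receives exactly
one feature identity: among overlapping features, the category ranking
first in the model's hierarchy wins, then largest overlap, then
lexicographic feature_id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import Feature, FeatureModel
from .readprep import UniqueReadTable

NO_HIT = "no-hit"
MULTI_HIT = "multi-hit"

class GenomeIndex:
    """Exact k-mer locus index over all contigs.

    Implemented as a lexicographically sorted array of all genomic
    k-mers (fixed-width bytes) with their origin positions; lookups are
    binary searches, and a k-mer is ambiguous iff it occupies more than
    one slot.
    """

    def __init__(self, genome: dict[str, str], k: int):
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.genome = genome
        self.contig_names = sorted(genome)
        kmer_blocks = []
        pos_blocks = []
        cid_blocks = []
        for ci, contig in enumerate(self.contig_names):
            seq = np.frombuffer(genome[contig].encode(), dtype=np.uint8)
            n = seq.size - k + 1
            if n <= 0:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(seq, k)
            kmer_blocks.append(np.ascontiguousarray(windows).view(f"S{k}")[:, 0])
            pos_blocks.append(np.arange(n, dtype=np.int64))
            cid_blocks.append(np.full(n, ci, dtype=np.int32))
        if kmer_blocks:
            kmers = np.concatenate(kmer_blocks)
            order = np.argsort(kmers, kind="stable")
            self._kmers = kmers[order]
            self._pos = np.concatenate(pos_blocks)[order]
            self._cid = np.concatenate(cid_blocks)[order]
        else:
            self._kmers = np.empty(0, dtype=f"S{k}")
            self._pos = np.empty(0, dtype=np.int64)
            self._cid = np.empty(0, dtype=np.int32)

    def lookup_many(self, seqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup of an ``S{k}`` array: returns (slot, n_hits);
        ``slot`` indexes the sorted k-mer table and is only meaningful
        where ``n_hits == 1``."""
        lo = np.searchsorted(self._kmers, seqs, side="left")
        n = self._kmers.size
        found = np.zeros(seqs.size, dtype=bool)
        in_range = lo < n
        found[in_range] = self._kmers[lo[in_range]] == seqs[in_range]
        # a second slot with the same k-mer means the hit is ambiguous
        # (counts are reported as 0, 1 or 2-meaning->=2)
        multi = np.zeros(seqs.size, dtype=bool)
        nxt = lo + 1
        ok = found & (nxt < n)
        multi[ok] = self._kmers[nxt[ok]] == seqs[ok]
        return lo, found.astype(np.int64) + multi.astype(np.int64)

    def lookup(self, seq: str):
        """Return (contig, position), ``None`` (absent) or the string
        'multi' for ambiguous k-mers."""
        key = np.array([seq.encode()], dtype=f"S{self.k}")
        lo, n = self.lookup_many(key)
        if n[0] == 0:
            return None
        if n[0] > 1:
            return "multi"
        j = int(lo[0])
        return self.contig_names[self._cid[j]], int(self._pos[j])

    def slot_locus(self, slots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(contig id, position) arrays for unique-hit slots."""
        return self._cid[slots], self._pos[slots]

    def is_unique_everywhere(self) -> bool:
        return not (self._kmers[1:] == self._kmers[:-1]).any()


@dataclass
class Placements:
    """Unique placements plus the unplaced tally.

    ``read_idx`` indexes rows of ``table``; ``start`` is 0-based and the
    interval is ``[start, start + table.read_length)``.
    """

    table: UniqueReadTable
    read_idx: np.ndarray
    contig: list[str]
    start: np.ndarray
    unplaced_idx: np.ndarray
    unplaced_reason: list[str]

    def unplaced_summary(self) -> pd.DataFrame:
        reasons = pd.Series(self.unplaced_reason, dtype="object")
        counts = self.table.counts[self.unplaced_idx].sum(axis=1)
        df = pd.DataFrame({"reason": reasons, "total_count": counts})
        return df.groupby("reason", as_index=False).agg(
            n_sequences=("reason", "size"), total_count=("total_count", "sum")
        )


def align_exact(
    table: UniqueReadTable, genome: dict[str, str], index: GenomeIndex | None = None
) -> Placements:
    """Place every unique read with exactly one exact genomic occurrence."""
    if table.read_length is None:
        return Placements(
            table, np.empty(0, int), [], np.empty(0, int), np.empty(0, int), []
        )
    if index is None:
        index = GenomeIndex(genome, table.read_length)
    elif index.k != table.read_length:
        raise ValueError(f"index k={index.k} != read length {table.read_length}")

    k = table.read_length
    seqs = getattr(table, "_seq_bytes", None)
    if seqs is None or seqs.dtype != np.dtype(f"S{k}"):
        seqs = np.array(table.sequences, dtype=f"S{k}")
    slots, n_hits = index.lookup_many(seqs)
    placed = n_hits == 1
    placed_idx = np.flatnonzero(placed)
    cid, pos = index.slot_locus(slots[placed])
    contigs = [index.contig_names[c] for c in cid.tolist()]
    un_idx = np.flatnonzero(~placed)
    un_reason = [
        NO_HIT if n == 0 else MULTI_HIT for n in n_hits[un_idx].tolist()
    ]
    return Placements(
        table,
        placed_idx.astype(np.int64),
        contigs,
        pos.astype(np.int64),
        un_idx.astype(np.int64),
        un_reason,
    )


@dataclass
class Assignment:
    """One feature identity per placed read.

    ``feature_idx`` indexes ``features`` (annotated features followed by
    synthesized intergenic catch-alls).
    """

    table: UniqueReadTable
    read_idx: np.ndarray
    contig: list[str]
    start: np.ndarray
    feature_idx: np.ndarray
    features: list[Feature]
    unplaced_idx: np.ndarray
    unplaced_reason: list[str]
    hierarchy: tuple[str, ...]

    @property
    def read_length(self) -> int:
        return self.table.read_length or 0

    def to_frame(self) -> pd.DataFrame:
        """BED-like table: contig, start, end, sequence, feature_id,
        gene_id, category, then one count column per sample."""
        feats = [self.features[j] for j in self.feature_idx]
        df = pd.DataFrame(
            {
                "contig": self.contig,
                "start": self.start,
                "end": self.start + self.read_length,
                "sequence": [self.table.sequences[i] for i in self.read_idx],
                "feature_id": [f.feature_id for f in feats],
                "gene_id": [f.gene_id for f in feats],
                "category": [f.category for f in feats],
            }
        )
        counts = pd.DataFrame(
            self.table.counts[self.read_idx], columns=self.table.samples,
            index=df.index,
        )
        return pd.concat([df, counts], axis=1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, model: FeatureModel) -> "Assignment":
        """Rebuild an assignment from its BED-like TSV representation."""
        meta = {"contig", "start", "end", "sequence", "feature_id", "gene_id",
                "category"}
        samples = [c for c in df.columns if c not in meta]
        table = UniqueReadTable(
            list(df["sequence"]), samples, df[samples].to_numpy()
        )
        features = list(model.features) + model.intergenic_features()
        by_id = {f.feature_id: j for j, f in enumerate(features)}
        try:
            fidx = np.array([by_id[fid] for fid in df["feature_id"]], dtype=np.int64)
        except KeyError as err:
            raise ValueError(f"feature {err.args[0]!r} absent from model") from None
        return cls(
            table,
            np.arange(len(df), dtype=np.int64),
            list(df["contig"]),
            df["start"].to_numpy(dtype=np.int64),
            fidx,
            features,
            np.empty(0, dtype=np.int64),
            [],
            model.hierarchy,
        )


def assign_identity(
    placements: Placements,
    model: FeatureModel,
    intergenic: bool = True,
) -> Assignment:
    """Resolve each placement to exactly one feature by the hierarchy.

    Deterministic regardless of feature input order: within the winning
    category the largest-overlap feature is taken, remaining ties broken
    by lexicographic feature_id. Without an intergenic catch-all a read
    overlapping nothing is a configuration error.
    """
    features = list(model.features)
    if intergenic:
        features += model.intergenic_features()
    rank = {cat: r for r, cat in enumerate(model.hierarchy)}

    # per-contig arrays sorted by (start, end, feature_id)
    per_contig: dict[str, tuple] = {}
    order_by_contig: dict[str, list[int]] = {}
    for j, f in enumerate(features):
        order_by_contig.setdefault(f.contig, []).append(j)
    for contig, idxs in order_by_contig.items():
        idxs.sort(key=lambda j: (features[j].start, features[j].end,
                                 features[j].feature_id))
        starts = np.array([features[j].start for j in idxs], dtype=np.int64)
        ends = np.array([features[j].end for j in idxs], dtype=np.int64)
        # running max of ends over strictly earlier-starting features
        prev_max_end = np.empty_like(ends)
        prev_max_end[0] = -1
        if len(ends) > 1:
            np.maximum.accumulate(ends[:-1], out=prev_max_end[1:])
        per_contig[contig] = (starts, ends, prev_max_end, np.asarray(idxs))

    rl = placements.table.read_length or 0
    n = len(placements.read_idx)
    feature_idx = np.full(n, -1, dtype=np.int64)
    contig_arr = np.asarray(placements.contig, dtype=object)
    for contig in per_contig:
        mask = contig_arr == contig
        if not mask.any():
            continue
        starts, ends, prev_max_end, idxs = per_contig[contig]
        s = placements.start[mask]
        e = s + rl
        j0 = np.searchsorted(starts, e, side="left") - 1
        j0c = np.maximum(j0, 0)
        # fast path: exactly one candidate feature, fully containing the read
        fast = (
            (j0 >= 0)
            & (starts[j0c] <= s)
            & (ends[j0c] >= e)
            & (prev_max_end[j0c] <= s)
        )
        out = np.full(s.size, -1, dtype=np.int64)
        out[fast] = idxs[j0c[fast]]
        for w in np.flatnonzero(~fast):
            out[w] = _resolve_slow(
                int(s[w]), int(e[w]), int(j0[w]), starts, ends, prev_max_end,
                idxs, features, rank,
            )
        feature_idx[mask] = out

    if (feature_idx < 0).any():
        bad = int(np.flatnonzero(feature_idx < 0)[0])
        raise ValueError(
            "read at "
            f"{placements.contig[bad]}:{int(placements.start[bad])} overlaps no "
            "feature and no intergenic catch-all is configured"
        )
    return Assignment(
        placements.table,
        placements.read_idx,
        placements.contig,
        placements.start,
        feature_idx,
        features,
        placements.unplaced_idx,
        placements.unplaced_reason,
        model.hierarchy,
    )


def _resolve_slow(s, e, j0, starts, ends, prev_max_end, idxs, features, rank):
    """Enumerate all features overlapping [s, e) and apply the hierarchy."""
    cands = []
    j = j0
    while j >= 0:
        if starts[j] < e and ends[j] > s:
            cands.append(j)
        if prev_max_end[j] <= s:
            break
        j -= 1
    if not cands:
        return -1
    best = min(
        cands,
        key=lambda j: (
            rank[features[idxs[j]].category],
            -(min(ends[j], e) - max(starts[j], s)),
            features[idxs[j]].feature_id,
        ),
    )
    return idxs[best]
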