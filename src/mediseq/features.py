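"""Genomic feature model and GFF3 interchange.

Coordinates are 0-based, half-open everywhere inside the package; GFF3
import/export converts to and from the standard's 1-based inclusive
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

CATEGORIES = ("miRNA", "exon", "intron", "intergenic")

#: Order in which overlapping categories win a read's identity.
DEFAULT_HIERARCHY = ("miRNA", "exon", "intron", "intergenic")

# feature category -> SO term used in GFF3 column 3
_SO_TYPE = {
    "exon": "exon",
    "intron": "intron",
    "miRNA": "miRNA",
    "intergenic": "intergenic_region",
}
_SO_TYPE_INV = {v: k for k, v in _SO_TYPE.items()}


@dataclass(frozen=True)
class Feature:
    """One annotated interval: ``[start, end)`` on ``contig``."""

    feature_id: str
    gene_id: str
    category: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown feature category {self.category!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"feature {self.feature_id}: bad interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class FeatureModel:
    """A set of features plus the category hierarchy used for assignment.

    ``contig_lengths`` lets the model synthesize intergenic catch-all
    features for positions not covered by any annotated feature.
    """

    features: list[Feature]
    contig_lengths: dict[str, int]
    hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY
    _intergenic_cache: list[Feature] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        present = {f.category for f in self.features} | {"intergenic"}
        missing = present - set(self.hierarchy)
        if missing:
            raise ValueError(f"hierarchy omits categories {sorted(missing)}")
        for f in self.features:
            clen = self.contig_lengths.get(f.contig)
            if clen is None:
                raise ValueError(f"feature {f.feature_id}: unknown contig {f.contig}")
            if f.end > clen:
                raise ValueError(
                    f"feature {f.feature_id} exceeds contig {f.contig} bounds"
                )

    # -- derived views -------------------------------------------------

    def by_contig(self) -> dict[str, list[Feature]]:
        out: dict[str, list[Feature]] = {c: [] for c in self.contig_lengths}
        for f in self.features:
            out[f.contig].append(f)
        for fs in out.values():
            fs.sort(key=lambda f: (f.start, f.end, f.feature_id))
        return out

    def intergenic_features(self) -> list[Feature]:
        """Catch-all features covering every position not inside an
        annotated feature, one per gap per contig."""
        if self._intergenic_cache is not None:
            return self._intergenic_cache
        out: list[Feature] = []
        for contig, feats in self.by_contig().items():
            clen = self.contig_lengths[contig]
            cursor = 0
            n = 0
            for f in feats:
                if f.start > cursor:
                    n += 1
                    out.append(
                        Feature(
                            f"{contig}.intergenic{n}", "intergenic", "intergenic",
                            contig, cursor, f.start,
                        )
                    )
                cursor = max(cursor, f.end)
            if cursor < clen:
                n += 1
                out.append(
                    Feature(
                        f"{contig}.intergenic{n}", "intergenic", "intergenic",
                        contig, cursor, clen,
                    )
                )
        self._intergenic_cache = out
        return out

    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.features:
            if f.category != "intergenic":
                seen.setdefault(f.gene_id)
        return list(seen)

    def gene_tracks(self, span: str = "exon") -> dict[str, list[Feature]]:
        """Features defining each gene's quantification track.

        ``span='exon'`` uses exon intervals for coding genes (miRNA rows
        use their own interval); ``span='full'`` uses every feature of the
        gene, introns included.
        """
        if span not in ("exon", "full"):
            raise ValueError("span must be 'exon' or 'full'")
        tracks: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.category == "intergenic":
                continue
            if f.category == "miRNA":
                tracks.setdefault(f.gene_id, []).append(f)
            elif span == "full" or f.category == "exon":
                tracks.setdefault(f.gene_id, []).append(f)
        for fs in tracks.values():
            fs.sort(key=lambda f: (f.contig, f.start))
        return tracks


# -- GFF3 I/O ----------------------------------------------------------


def gene_spans(model: FeatureModel) -> dict[str, tuple[str, int, int]]:
    """Span (contig, start, end) of each exon-bearing gene."""
    spans: dict[str, tuple[str, int, int]] = {}
    for f in model.features:
        if f.category not in ("exon", "intron"):
            continue
        cur = spans.get(f.gene_id)
        if cur is None:
            spans[f.gene_id] = (f.contig, f.start, f.end)
        else:
            spans[f.gene_id] = (cur[0], min(cur[1], f.start), max(cur[2], f.end))
    return spans


def write_gff3(model: FeatureModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in sorted(model.contig_lengths.items()):
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for gene_id, (contig, start, end) in sorted(
            gene_spans(model).items(), key=lambda kv: (kv[1][0], kv[1][1], kv[0])
        ):
            fh.write(
                "\t".join(
                    (contig, "mediseq", "gene", str(start + 1), str(end), ".",
                     "+", ".", f"ID={gene_id};gene_id={gene_id}")
                )
                + "\n"
            )
        for f in sorted(
            model.features, key=lambda f: (f.contig, f.start, f.end, f.feature_id)
        ):
            attrs = f"ID={f.feature_id};gene_id={f.gene_id}"
            fh.write(
                "\t".join(
                    (
                        f.contig,
                        "mediseq",
                        _SO_TYPE[f.category],
                        str(f.start + 1),  # 1-based inclusive
                        str(f.end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    )
                )
                + "\n"
            )


def read_gff3(path, hierarchy: Sequence[str] = DEFAULT_HIERARCHY) -> FeatureModel:
    features: list[Feature] = []
    contig_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                _, contig, _, end = line.split()[:4]
                contig_lengths[contig] = int(end)
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, so_type, start, end, _, _, _, attrs = cols
            if so_type == "gene":
                continue  # gene records are containers; intervals come from parts
            category = _SO_TYPE_INV.get(so_type)
            if category is None:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            features.append(
                Feature(
                    attr.get("ID", f"{contig}:{start}-{end}"),
                    attr.get("gene_id", attr.get("ID", "NA")),
                    category,
                    contig,
                    int(start) - 1,
                    int(end),
                )
            )
    if not contig_lengths:
        for f in features:
            contig_lengths[f.contig] = max(contig_lengths.get(f.contig, 0), f.end)
    return FeatureModel(features, contig_lengths, tuple(hierarchy))
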