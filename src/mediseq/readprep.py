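"""Read trimming and duplicate compression.

Reads are positionally trimmed (a fixed number of nucleotides off each
end), then collapsed to a table of distinct sequences with per-sample
occurrence counts. Quality strings are ignored after trimming; reads
containing N are kept unless explicitly dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_TRIM = 2  # nt removed from each end

TABLE_DIALECT = "mediseq-unique-reads-v1"  # sequence column + one count column/sample


@dataclass
class TrimStats:
    kept: int = 0
    rejected: int = 0  # reads shorter than left + right + 1


def trim_reads(
    reads: Iterable[str],
    left: int = DEFAULT_TRIM,
    right: int = DEFAULT_TRIM,
    stats: TrimStats | None = None,
    expected_length: int | None = None,
) -> Iterator[str]:
    """Yield ``read[left : len(read) - right]`` for each read, in order.

    Reads too short to survive trimming are dropped and tallied in
    ``stats.rejected``. If ``expected_length`` is given and the trimmed
    length disagrees, a warning is logged once (never silently adjusted).
    """
    if left < 0 or right < 0:
        raise ValueError("trim amounts must be non-negative")
    warned = False
    for read in reads:
        if len(read) < left + right + 1:
            if stats is not None:
                stats.rejected += 1
            continue
        trimmed = read[left : len(read) - right] if right else read[left:]
        if (
            expected_length is not None
            and not warned
            and len(trimmed) != expected_length
        ):
            log.warning(
                "trimmed length %d differs from expected %d (input %d, trims %d/%d)",
                len(trimmed), expected_length, len(read), left, right,
            )
            warned = True
        if stats is not None:
            stats.kept += 1
        yield trimmed


@dataclass
class UniqueReadTable:
    """Distinct read sequences with per-sample occurrence counts.

    ``counts[i, j]`` is how many times ``sequences[i]`` occurred in
    ``samples[j]``; absent combinations are 0.
    """

    sequences: list[str]
    samples: list[str]
    counts: np.ndarray  # (n_sequences, n_samples) non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sequences), len(self.samples)):
            raise ValueError("counts shape does not match sequences x samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.sequences:
            lengths = {len(s) for s in self.sequences}
            if len(lengths) > 1:
                raise ValueError(f"mixed sequence lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def read_length(self) -> int | None:
        return len(self.sequences[0]) if self.sequences else None

    def total_counts(self) -> dict[str, int]:
        sums = self.counts.sum(axis=0)
        return {s: int(sums[j]) for j, s in enumerate(self.samples)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.sequences, name="sequence"),
            columns=self.samples,
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "UniqueReadTable":
        df = pd.read_csv(path, sep="\t", index_col="sequence")
        return cls(list(df.index), list(df.columns), df.to_numpy())


def deduplicate(
    reads_by_sample: Mapping[str, Iterable[str]],
    drop_ambiguous: bool = False,
) -> UniqueReadTable:
    """Collapse identical sequences, keeping per-sample occurrence counts.

    All reads must share one length; a mixed-length stream raises with
    the offending sequence named. ``drop_ambiguous`` discards reads
    containing N before counting.
    """
    samples = list(reads_by_sample)
    counters: list[Counter] = []
    length: int | None = None
    for sample in samples:
        # Counter over the raw stream is C-speed; lengths are validated
        # on the (much smaller) set of distinct sequences afterwards.
        c = Counter(reads_by_sample[sample])
        if drop_ambiguous:
            for seq in [s for s in c if "N" in s]:
                del c[seq]
        for seq in c:
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"sample {sample!r}: read of length {len(seq)} "
                    f"(expected {length}): {seq[:20]}..."
                )
        counters.append(c)

    index: dict[str, int] = {}
    for c in counters:
        for seq in c:
            if seq not in index:
                index[seq] = len(index)
    counts = np.zeros((len(index), len(samples)), dtype=np.int64)
    for j, c in enumerate(counters):
        for seq, n in c.items():
            counts[index[seq], j] = n
    return UniqueReadTable(list(index), samples, counts)
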