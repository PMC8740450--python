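"""Core domain types for amplicon preprocessing.

The central objects are a sequencing read (:class:`FastqRecord`), the
sample-to-barcode map (:class:`SampleMetadata`), and the ASV count matrix
(:class:`FeatureTable`, a thin wrapper around a features x samples pandas
DataFrame with an optional feature-to-sequence map).  Detection results
(orientation, high-quality region, depth selection) are small frozen records
so they can be logged and serialized verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MetadataError

NUCLEOTIDES = frozenset("ACGTN")

MAX_PHRED = 93  # '~' (126) - 33, the top of the Phred+33 printable range


@dataclass(frozen=True, slots=True)
class FastqRecord:
    """One sequencing read: identifier, bases, and per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self):
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        for q in self.quals:
            if not 0 <= q <= MAX_PHRED:
                raise ValueError(
                    f"read {self.read_id!r}: Phred score {q} outside [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def trim_prefix(self, n: int) -> "FastqRecord":
        """Return a copy with the first ``n`` bases and their qualities removed."""
        return FastqRecord(self.read_id, self.bases[n:], self.quals[n:])


class SampleMetadata:
    """Ordered sample-id -> barcode map with QIIME-style invariants.

    Sample ids and barcodes must both be unique, barcodes must share one
    length and use only A/C/G/T.  Barcode case is normalized to upper.
    """

    def __init__(self, records: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = list(records.items()) if isinstance(records, Mapping) else list(records)
        self._records: dict[str, str] = {}
        seen_barcodes: dict[str, str] = {}
        for sample_id, barcode in items:
            barcode = barcode.upper()
            if sample_id in self._records:
                raise MetadataError(f"duplicate sample id {sample_id!r}")
            if not barcode:
                raise MetadataError(f"sample {sample_id!r} has an empty barcode")
            if set(barcode) - set("ACGT"):
                raise MetadataError(
                    f"sample {sample_id!r}: barcode {barcode!r} contains "
                    "characters outside A/C/G/T"
                )
            if barcode in seen_barcodes:
                raise MetadataError(
                    f"duplicate barcode {barcode!r} (samples "
                    f"{seen_barcodes[barcode]!r} and {sample_id!r})"
                )
            seen_barcodes[barcode] = sample_id
            self._records[sample_id] = barcode
        if not self._records:
            raise MetadataError("metadata contains no samples")
        lengths = {len(b) for b in self._records.values()}
        if len(lengths) > 1:
            raise MetadataError(f"barcodes have unequal lengths: {sorted(lengths)}")

    @property
    def records(self) -> dict[str, str]:
        return dict(self._records)

    @property
    def sample_ids(self) -> list[str]:
        return list(self._records)

    @property
    def barcodes(self) -> list[str]:
        return list(self._records.values())

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self._records.values())))

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMetadata) and self._records == other._records


class FeatureTable:
    """Integer count matrix of features (ASVs) x samples.

    Wraps a pandas DataFrame whose index holds feature ids and whose columns
    hold sample ids, plus an optional ``feature_seqs`` map from feature id to
    representative sequence.  Counts are validated to be non-negative
    integers and ids to be unique.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        feature_seqs: Mapping[str, str] | None = None,
    ):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                if not np.all(values == np.floor(values)):
                    raise ValueError("counts must be integers")
            if (values < 0).any():
                raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        self.counts.index = self.counts.index.astype(str)
        self.counts.columns = self.counts.columns.astype(str)
        self.counts.index.name = "feature-id"
        if feature_seqs is not None:
            feature_seqs = {str(k): str(v).upper() for k, v in feature_seqs.items()}
            missing = set(self.counts.index) - set(feature_seqs)
            if missing:
                raise ValueError(
                    f"feature_seqs missing sequences for {sorted(missing)}"
                )
        self.feature_seqs = feature_seqs

    @property
    def feature_ids(self) -> list[str]:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.counts.columns.tolist()

    @property
    def sample_totals(self) -> pd.Series:
        """Column sums: total reads per sample."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum()) if self.counts.size else 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.feature_seqs == other.feature_seqs
        )

    def sorted(self) -> "FeatureTable":
        """Canonical ordering: features by descending total then id; samples by id."""
        totals = self.counts.sum(axis=1)
        order = sorted(self.counts.index, key=lambda f: (-totals[f], f))
        return FeatureTable(
            self.counts.loc[order, sorted(self.counts.columns)],
            self.feature_seqs,
        )


@dataclass(frozen=True, slots=True)
class OrientationResult:
    """Outcome of the barcode-orientation test.

    ``n_same`` counts reads whose 5' prefix exactly equals a metadata
    barcode; ``n_revcomp`` counts prefixes equal to a reverse-complemented
    barcode.  The decision is ``same`` only when n_same strictly exceeds
    ratio x n_revcomp (and symmetrically for ``reverse_complement``);
    anything else is ``ambiguous``.
    """

    n_same: int
    n_revcomp: int
    decision: str  # "same" | "reverse_complement" | "ambiguous"
    ratio: float = 10.0
    n_reads: int = 0


@dataclass(slots=True)
class DemuxResult:
    """Per-sample read assignments with barcodes cut out.

    ``unassigned_records`` keeps the non-matching reads verbatim (no
    trimming) so they can be written out for inspection.
    """

    assignments: dict[str, list[FastqRecord]]
    n_unassigned: int
    unassigned_records: list[FastqRecord] = field(default_factory=list)

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assignments.values())


@dataclass(frozen=True, slots=True)
class QualityProfile:
    """Per-position aggregate quality across a read set.

    ``medians[p-1]`` is the median Phred score at 1-based position ``p``,
    taken over every read long enough to cover that position; ``smoothed``
    is its moving average and ``n_reads_at_position`` the coverage count.
    """

    medians: tuple[float, ...]
    smoothed: tuple[float, ...]
    n_reads_at_position: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.medians)


@dataclass(frozen=True, slots=True)
class HQRegion:
    """1-based inclusive coordinates of the selected high-quality window."""

    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid region ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class DepthSelection:
    """The chosen rarefaction depth and what it retains.

    ``candidates`` records every evaluated (depth, n_samples, total) triple
    so the choice can be audited; ``total_retained`` is always
    depth * len(retained).
    """

    depth: int
    retained: tuple[str, ...]
    candidates: tuple[tuple[int, int, int], ...] = field(default=())

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def total_retained(self) -> int:
        return self.depth * len(self.retained)
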