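"""Synthetic multiplexed sequencing runs and feature tables.

Every detection algorithm in this package is exercised on generated data
with known ground truth, so no download is ever needed.  A simulated run
emulates the structure the detectors assume: equal-length unique 5' sample
barcodes (as written or reverse-complemented), uniform random template
bases, and per-base Phred scores drawn from a Gaussian around a
deterministic per-position mean curve — a flat plateau, an optional linear
3' decay, and optional isolated single-position dips of the kind a moving
average is meant to ride over.  Scores are clamped to the Illumina binned
range [2, 41] and rounded.

Defaults mirror a small modern 16S run: 40 samples, 12-nt barcodes, 150-bp
reads, per-sample read counts log-uniform between 200 and 1000 (a right-
skewed spread whose shallow half drives depth optimization), 98% of reads
with an intact barcode, plateau Q38 with noise sd 2 and a 3' decay of
0.4 Phred/position starting at position 110.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np

from .orientation import reverse_complement
from .types import FastqRecord, FeatureTable, SampleMetadata

import pandas as pd


@dataclass(frozen=True, slots=True)
class QualityModel:
    """Deterministic per-position mean Phred curve plus Gaussian noise.

    The mean sits at ``plateau`` until ``decay_start`` (1-based), then
    falls linearly by ``decay_slope`` Phred per position.  Positions listed
    in ``dip_positions`` (1-based) have their mean lowered by ``dip_depth``.
    Per-read scores add N(0, noise_sd) noise, then are clamped to [2, 41]
    and rounded to integers.
    """

    plateau: float = 38.0
    noise_sd: float = 2.0
    decay_start: int | None = 110
    decay_slope: float = 0.4
    dip_positions: tuple[int, ...] = ()
    dip_depth: float = 10.0

    def mean_curve(self, length: int) -> np.ndarray:
        pos = np.arange(1, length + 1)
        curve = np.full(length, self.plateau, dtype=float)
        if self.decay_start is not None:
            over = pos > self.decay_start
            curve[over] -= self.decay_slope * (pos[over] - self.decay_start)
        for p in self.dip_positions:
            if 1 <= p <= length:
                curve[p - 1] -= self.dip_depth
        return curve

    def hq_end(self, length: int, cutoff: float = 30.0) -> int:
        """Last position whose noise-free mean (ignoring dips) exceeds cutoff."""
        curve = QualityModel(
            self.plateau, 0.0, self.decay_start, self.decay_slope
        ).mean_curve(length)
        above = np.nonzero(curve > cutoff)[0]
        if above.size == 0:
            return 0
        return int(above[-1]) + 1


@dataclass(frozen=True, slots=True)
class SimSpec:
    """Parameters of one simulated multiplexed run.

    ``reads_per_sample`` accepts an int (uniform across samples), an
    explicit per-sample sequence, or a (low, high) pair meaning per-sample
    totals drawn log-uniformly between the bounds.
    """

    n_samples: int = 40
    reads_per_sample: int | tuple[int, int] | Sequence[int] = (200, 1000)
    read_length: int = 150
    barcode_length: int = 12
    orientation: str = "same"  # "same" | "reverse_complement"
    barcode_intact_frac: float = 0.98
    quality_model: QualityModel = field(default_factory=QualityModel)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0 or self.read_length <= 0 or self.barcode_length <= 0:
            raise ValueError("n_samples, read_length and barcode_length must be > 0")
        if not 0.0 <= self.barcode_intact_frac <= 1.0:
            raise ValueError("barcode_intact_frac must lie in [0, 1]")
        if self.orientation not in ("same", "reverse_complement"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.barcode_length > self.read_length:
            raise ValueError("barcode cannot be longer than the read")


@dataclass(frozen=True, slots=True)
class GroundTruth:
    """What the simulator knows that the detectors must recover."""

    labels: tuple[str | None, ...]  # per-read true sample; None = corrupted barcode
    orientation: str
    quality_mean: tuple[float, ...]  # noise-free mean curve over read positions
    hq_end: int  # last position with noise-free mean > Q30 (ignoring dips)


_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _random_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Draw unique equal-length barcodes, orientation-distinguishable.

    Mirrors how real barcode kits are designed: no barcode is its own
    reverse complement and no two barcodes are reverse complements of each
    other, so the as-written and reverse-complemented barcode sets never
    overlap and orientation detection is well-posed.
    """
    if n > 4**length:
        raise ValueError(
            f"cannot draw {n} distinct barcodes of length {length} "
            f"(only {4 ** length} exist)"
        )
    barcodes: list[str] = []
    forbidden: set[str] = set()

    def admissible(b: str) -> bool:
        return b not in forbidden and reverse_complement(b) != b

    if 4**length <= 65536:  # small space: shuffle the whole universe
        universe = ["".join(p) for p in product("ACGT", repeat=length)]
        rng.shuffle(universe)
        for b in universe:
            if admissible(b):
                barcodes.append(b)
                forbidden.update((b, reverse_complement(b)))
                if len(barcodes) == n:
                    return barcodes
        raise ValueError(
            f"cannot draw {n} orientation-distinguishable barcodes of "
            f"length {length}"
        )
    while len(barcodes) < n:
        b = "".join(rng.choice(_BASES, size=length))
        if admissible(b):
            barcodes.append(b)
            forbidden.update((b, reverse_complement(b)))
    return barcodes


def _resolve_totals(spec: SimSpec, rng: np.random.Generator) -> list[int]:
    r = spec.reads_per_sample
    if isinstance(r, int):
        return [r] * spec.n_samples
    if isinstance(r, tuple) and len(r) == 2:
        lo, hi = r
        draws = np.exp(rng.uniform(math.log(lo), math.log(hi), size=spec.n_samples))
        return [int(round(d)) for d in draws]
    r = list(r)
    if len(r) != spec.n_samples:
        raise ValueError(
            f"reads_per_sample sequence has {len(r)} entries for "
            f"{spec.n_samples} samples"
        )
    return [int(x) for x in r]


def simulate_run(
    spec: SimSpec,
) -> tuple[list[FastqRecord], SampleMetadata, GroundTruth]:
    """Generate one multiplexed run with ground truth; fully seeded.

    Each read is the (oriented) sample barcode followed by random template
    bases, with qualities drawn from the spec's quality model.  With
    probability ``1 - barcode_intact_frac`` the barcode prefix is corrupted
    by a point substitution chosen so the prefix matches no barcode in
    either orientation; such reads carry a ``None`` ground-truth label.
    """
    rng = np.random.default_rng(spec.seed)
    barcodes = _random_barcodes(rng, spec.n_samples, spec.barcode_length)
    sample_ids = [f"sample{i + 1:03d}" for i in range(spec.n_samples)]
    meta = SampleMetadata(zip(sample_ids, barcodes))
    forbidden = set(barcodes) | {reverse_complement(b) for b in barcodes}

    totals = _resolve_totals(spec, rng)
    mean_curve = spec.quality_model.mean_curve(spec.read_length)
    template_len = spec.read_length - spec.barcode_length

    records: list[FastqRecord] = []
    labels: list[str | None] = []
    read_no = 0
    for sample_id, barcode, n_reads in zip(sample_ids, barcodes, totals):
        oriented = (
            barcode
            if spec.orientation == "same"
            else reverse_complement(barcode)
        )
        for _ in range(n_reads):
            read_no += 1
            prefix = oriented
            label: str | None = sample_id
            if rng.random() > spec.barcode_intact_frac:
                prefix = _corrupt(prefix, forbidden, rng)
                label = None
            template = "".join(rng.choice(_BASES, size=template_len))
            quals = np.clip(
                np.rint(mean_curve + rng.normal(0.0, spec.quality_model.noise_sd,
                                                size=spec.read_length)),
                2,
                41,
            ).astype(int)
            records.append(
                FastqRecord(f"read{read_no:06d}", prefix + template, tuple(quals))
            )
            labels.append(label)
    truth = GroundTruth(
        labels=tuple(labels),
        orientation=spec.orientation,
        quality_mean=tuple(float(x) for x in mean_curve),
        hq_end=spec.quality_model.hq_end(spec.read_length),
    )
    return records, meta, truth


def _corrupt(barcode: str, forbidden: set[str], rng: np.random.Generator) -> str:
    """Point-mutate until the prefix matches no barcode in any orientation."""
    while True:
        pos = int(rng.integers(len(barcode)))
        alternatives = [b for b in "ACGT" if b != barcode[pos]]
        mutated = (
            barcode[:pos] + alternatives[int(rng.integers(3))] + barcode[pos + 1:]
        )
        if mutated not in forbidden:
            return mutated


def simulate_feature_table(
    n_features: int,
    n_samples: int,
    depth_distribution: int | tuple[int, int] | Sequence[int] = (200, 1000),
    seed: int = 0,
    weight_sigma: float = 2.0,
    sample_prefix: str = "sample",
    feature_prefix: str = "asv",
) -> FeatureTable:
    """Generate a random ASV feature table with representative sequences.

    Feature abundance weights are heavy-tailed (log-normal with shape
    ``weight_sigma``); each sample's total read count follows
    ``depth_distribution`` (an int, an explicit per-sample sequence, or a
    (low, high) log-uniform pair) and its counts are a multinomial draw
    over the feature weights.  Fully seeded.  ``sample_prefix`` and
    ``feature_prefix`` namespace the ids so tables emulating separate runs
    can be merged without id collisions.
    """
    if n_features <= 0 or n_samples <= 0:
        raise ValueError("n_features and n_samples must be positive")
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(mean=0.0, sigma=weight_sigma, size=n_features)
    weights /= weights.sum()
    if isinstance(depth_distribution, int):
        totals = [depth_distribution] * n_samples
    elif isinstance(depth_distribution, tuple) and len(depth_distribution) == 2:
        lo, hi = depth_distribution
        totals = [
            int(round(t))
            for t in np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_samples))
        ]
    else:
        totals = [int(t) for t in depth_distribution]
        if len(totals) != n_samples:
            raise ValueError(
                f"depth_distribution has {len(totals)} entries for "
                f"{n_samples} samples"
            )
    counts = np.column_stack([rng.multinomial(t, weights) for t in totals])
    feature_ids = [f"{feature_prefix}{i + 1:04d}" for i in range(n_features)]
    sample_ids = [f"{sample_prefix}{j + 1:03d}" for j in range(n_samples)]
    seqs = {
        fid: "".join(rng.choice(_BASES, size=120)) for fid in feature_ids
    }
    df = pd.DataFrame(counts, index=feature_ids, columns=sample_ids)
    return FeatureTable(df, seqs)
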