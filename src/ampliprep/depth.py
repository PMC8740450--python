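"""Rarefaction-depth optimization and rarefaction.

Rarefying a feature table to a common depth removes library-size bias but
forces a trade-off: a deep cutoff discards shallow samples, a shallow cutoff
discards reads from deep ones.  The optimizer scans the sample read counts
from the median down to the minimum, treating each such count R_i as a
candidate depth, and picks the one maximizing the total number of retained
reads R_i * N_i, where N_i is the number of samples with at least R_i reads.
Restricting candidates to counts at or below the median guarantees at least
half the samples survive.

Rarefaction itself is uniform subsampling without replacement: each retained
sample's reads are drawn from its count vector via a multivariate
hypergeometric draw, so every retained column sums exactly to the depth.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DepthError
from .types import DepthSelection, FeatureTable


def optimize_depth(counts: Mapping[str, int] | pd.Series) -> DepthSelection:
    """Choose the rarefaction depth maximizing total retained reads.

    Parameters
    ----------
    counts
        Map sample id -> total read count (the column sums of a feature
        table).

    The candidate depths are the distinct counts of samples whose counts lie
    at or below the median count (median of an even-sized set = mean of the
    two central values).  For each candidate depth d, N(d) is the number of
    samples with count >= d; the returned selection maximizes d * N(d),
    with ties broken toward the larger depth.  The full candidate trace is
    kept on the result for auditing.
    """
    series = pd.Series(dict(counts), dtype="int64")
    if series.empty or (series <= 0).all():
        raise DepthError("no sample has a positive read count")
    values = series.to_numpy()
    median = float(np.median(values))
    candidates = sorted(
        {int(c) for c in values if c <= median and c > 0}, reverse=True
    )
    if not candidates:
        # every positive count sits above the median: only possible when most
        # counts are zero; fall back to the smallest positive count
        candidates = [int(values[values > 0].min())]
    trace: list[tuple[int, int, int]] = []
    best: tuple[int, int, int] | None = None
    for d in candidates:  # descending, so strict '>' breaks ties to larger d
        n = int((values >= d).sum())
        total = d * n
        trace.append((d, n, total))
        if best is None or total > best[2]:
            best = (d, n, total)
    depth = best[0]
    retained = tuple(s for s, c in series.items() if c >= depth)
    return DepthSelection(depth=depth, retained=retained, candidates=tuple(trace))


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Rarefy a feature table to ``depth`` reads per sample.

    Samples with fewer than ``depth`` total reads are dropped; each
    remaining sample is subsampled uniformly without replacement to exactly
    ``depth`` reads (multivariate hypergeometric draw over its feature
    counts).  Deterministic for a given seed, table and depth.
    """
    if depth <= 0:
        raise DepthError(f"rarefaction depth must be positive, got {depth}")
    totals = table.sample_totals
    keep = [s for s in table.sample_ids if totals[s] >= depth]
    if not keep:
        raise DepthError(
            f"no sample reaches depth {depth} (max total is "
            f"{int(totals.max()) if len(totals) else 0})"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in keep:  # fixed sample order makes the draw reproducible
        column = table.counts[sample].to_numpy()
        out[sample] = rng.multivariate_hypergeometric(column, depth)
    rarefied = pd.DataFrame(out, index=table.counts.index, columns=keep)
    return FeatureTable(rarefied, table.feature_seqs)
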