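"""Merging feature tables from multiple sequencing runs.

Because ASVs are exact sequences, tables from separate runs can be combined
without re-clustering: features whose representative sequences are identical
(case-insensitive) are the same biological variant and their counts are
summed per sample.  Sample sets must be disjoint across runs — the same
sample id appearing twice almost always signals a metadata mistake, so it is
an error rather than a silent sum.  When no representative sequences are
attached, features merge by id instead.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .errors import MergeError
from .types import FeatureTable


def merge_feature_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Merge feature tables into one; see module docstring for semantics.

    The merged id of a collapsed feature is the lexicographically first
    contributing id; output rows are ordered by descending total count,
    ties by id, and columns are sorted by sample id.  Features
    absent from a run get zero counts in that run's samples.  Total counts
    are conserved exactly.
    """
    if not tables:
        raise MergeError("nothing to merge: empty table list")
    seen_samples: dict[str, int] = {}
    for i, t in enumerate(tables):
        for s in t.sample_ids:
            if s in seen_samples:
                raise MergeError(
                    f"sample id {s!r} appears in tables {seen_samples[s]} and {i}"
                )
            seen_samples[s] = i

    use_seqs = all(t.feature_seqs is not None for t in tables)
    # one consistency pass over ids regardless of merge key: the same feature
    # id bound to two different sequences is always an error
    id_to_seq: dict[str, str] = {}
    for t in tables:
        for fid, seq in (t.feature_seqs or {}).items():
            if fid in id_to_seq and id_to_seq[fid] != seq:
                raise MergeError(
                    f"feature id {fid!r} is bound to different sequences in "
                    "different tables"
                )
            id_to_seq.setdefault(fid, seq)

    # key features by sequence (collapsing identical ASVs) or by id
    key_of = (lambda t, fid: t.feature_seqs[fid]) if use_seqs else (lambda t, fid: fid)
    merged_id: dict[str, str] = {}  # key -> representative feature id
    for t in tables:
        for fid in t.feature_ids:
            k = key_of(t, fid)
            if k not in merged_id or fid < merged_id[k]:
                merged_id[k] = fid

    sample_order = list(seen_samples)
    frames = []
    for t in tables:
        df = t.counts.copy()
        df.index = [merged_id[key_of(t, fid)] for fid in t.feature_ids]
        frames.append(df.groupby(level=0).sum())  # collapse within one table too
    merged = (
        pd.concat(frames, axis=1)
        .fillna(0)
        .astype("int64")
        .reindex(columns=sample_order)
    )
    feature_seqs = None
    if use_seqs:
        feature_seqs = {fid: key for key, fid in merged_id.items()}
    elif any(t.feature_seqs for t in tables):
        # partial sequence information: keep what is known, id-keyed merge
        feature_seqs = None
    return FeatureTable(merged, feature_seqs).sorted()
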