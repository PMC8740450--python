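import numpy as np
import pandas as pd
import pytest

from ampliprep import FastqRecord, FeatureTable, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def meta_two():
    return SampleMetadata({"s1": "ACGTA", "s2": "TTGCA"})


def make_read(bases: str, qual: int | list[int] = 38, read_id: str = "r") -> FastqRecord:
    quals = [qual] * len(bases) if isinstance(qual, int) else list(qual)
    return FastqRecord(read_id, bases, tuple(quals))


def make_table(columns: dict[str, list[int]], feature_ids: list[str],
               seqs: dict[str, str] | None = None) -> FeatureTable:
    return FeatureTable(pd.DataFrame(columns, index=feature_ids), seqs)


def write_fastq_text(path, records):
    with open(path, "w") as fh:
        for read_id, bases, qual in records:
            fh.write(f"@{read_id}\n{bases}\n+\n{qual}\n")
    return path


def write_metadata_text(path, rows, header=("sample-id", "barcode-sequence")):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path
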