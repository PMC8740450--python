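"""Barcode-orientation detection and demultiplexing behaviour."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ampliprep as ap
from ampliprep.errors import AmbiguousOrientationError

from .conftest import make_read


@pytest.mark.parametrize(
    "seq, expected",
    [("ACGTA", "TACGT"), ("", ""), ("ACN", "NGT"), ("AAAA", "TTTT")],
)
def test_reverse_complement(seq, expected):
    assert ap.reverse_complement(seq) == expected


def test_reverse_complement_rejects_non_nucleotides():
    with pytest.raises(ValueError, match="non-nucleotide"):
        ap.reverse_complement("ACGU")


class TestDetectOrientation:
    """The decision requires one orientation to dominate strictly >10-fold."""

    @staticmethod
    def _reads(n_same, n_rc, n_other, barcode="ACGTA"):
        rc = ap.reverse_complement(barcode)
        reads = [make_read(barcode + "GG") for _ in range(n_same)]
        reads += [make_read(rc + "GG") for _ in range(n_rc)]
        reads += [make_read("TTTTTGG") for _ in range(n_other)]
        return reads

    def test_dominant_same(self, meta_two):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        result = ap.detect_orientation(iter(self._reads(110, 10, 30)), meta)
        assert (result.n_same, result.n_revcomp) == (110, 10)
        assert result.decision == "same"  # 110 > 10*10

    def test_boundary_is_ambiguous(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        result = ap.detect_orientation(iter(self._reads(100, 10, 0)), meta)
        assert (result.n_same, result.n_revcomp) == (100, 10)
        assert result.decision == "ambiguous"  # 100 is not strictly > 100

    def test_no_matches_is_ambiguous(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        result = ap.detect_orientation(iter(self._reads(0, 0, 5)), meta)
        assert (result.n_same, result.n_revcomp, result.decision) == (
            0, 0, "ambiguous",
        )

    def test_dominant_revcomp(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        result = ap.detect_orientation(iter(self._reads(0, 11, 0)), meta)
        assert result.decision == "reverse_complement"

    def test_empty_stream_errors(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        with pytest.raises(ValueError, match="empty"):
            ap.detect_orientation(iter([]), meta)

    def test_reads_shorter_than_barcode_count_as_nonmatching(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        reads = [make_read("ACG"), make_read("ACGTAGG")]
        result = ap.detect_orientation(iter(reads), meta)
        assert (result.n_same, result.n_reads) == (1, 2)

    def test_max_reads_caps_inspection(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        reads = self._reads(5, 0, 0) + self._reads(0, 50, 0)
        result = ap.detect_orientation(iter(reads), meta, max_reads=5)
        assert (result.n_same, result.n_revcomp, result.n_reads) == (5, 0, 5)

    def test_metadata_flip_symmetry(self):
        """Reverse-complementing the metadata barcodes flips the decision."""
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        flipped = ap.SampleMetadata({"s1": ap.reverse_complement("ACGTA")})
        reads = self._reads(110, 10, 30)
        fwd = ap.detect_orientation(iter(reads), meta)
        rev = ap.detect_orientation(iter(reads), flipped)
        assert fwd.decision == "same"
        assert rev.decision == "reverse_complement"
        assert (rev.n_same, rev.n_revcomp) == (fwd.n_revcomp, fwd.n_same)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=5, max_size=5), min_size=1, max_size=40))
    def test_read_flip_symmetry_on_barcode_length_reads(self, bases_list):
        """On reads exactly one barcode long, reverse-complementing every read
        swaps the two orientation counts (and leaves ambiguity fixed)."""
        meta = ap.SampleMetadata({"s1": "ACGTA", "s2": "GGGGG"})
        reads = [make_read(b) for b in bases_list]
        flipped = [make_read(ap.reverse_complement(b)) for b in bases_list]
        fwd = ap.detect_orientation(iter(reads), meta)
        rev = ap.detect_orientation(iter(flipped), meta)
        assert (rev.n_same, rev.n_revcomp) == (fwd.n_revcomp, fwd.n_same)
        if fwd.decision == "ambiguous":
            assert rev.decision == "ambiguous"
        elif fwd.decision == "same":
            assert rev.decision == "reverse_complement"
        else:
            assert rev.decision == "same"


class TestDemultiplex:
    def test_prefix_match_and_trim(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        reads = [make_read("ACGTAGGG", read_id=f"r{i}") for i in range(3)]
        result = ap.demultiplex(iter(reads), meta, "same")
        assert [r.bases for r in result.assignments["s1"]] == ["GGG"] * 3
        assert all(len(r.quals) == 3 for r in result.assignments["s1"])
        assert result.n_unassigned == 0

    def test_revcomp_orientation_uses_complemented_barcodes(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        reads = [make_read(ap.reverse_complement("ACGTA") + "CCC")]
        result = ap.demultiplex(iter(reads), meta, "reverse_complement")
        assert [r.bases for r in result.assignments["s1"]] == ["CCC"]

    def test_nonmatching_read_unassigned(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        result = ap.demultiplex(iter([make_read("TTTTTTTT")]), meta, "same")
        assert result.n_unassigned == 1
        assert result.n_assigned == 0

    def test_zero_reads(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        result = ap.demultiplex(iter([]), meta, "same")
        assert result.n_unassigned == 0
        assert all(v == [] for v in result.assignments.values())

    def test_ambiguous_orientation_rejected(self):
        meta = ap.SampleMetadata({"s1": "ACGTA"})
        with pytest.raises(ValueError, match="orientation"):
            ap.demultiplex(iter([]), meta, "ambiguous")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["same", "reverse_complement"]))
    def test_read_conservation(self, seed, orientation):
        """assigned + unassigned == input count, whatever the inputs."""
        spec = ap.SimSpec(
            n_samples=3, reads_per_sample=20, read_length=30,
            barcode_length=6, orientation=orientation,
            barcode_intact_frac=0.8, seed=seed,
        )
        records, meta, _ = ap.simulate_run(spec)
        result = ap.demultiplex(iter(records), meta, orientation)
        assert result.n_assigned + result.n_unassigned == len(records)


def test_demultiplex_barcode_file_pairs_by_record_order():
    meta = ap.SampleMetadata({"s1": "ACGTA", "s2": "TTGCA"})
    barcode_reads = [make_read("ACGTA"), make_read("TTGCA"), make_read("GGGGG")]
    bio_reads = [make_read("AAAA", read_id=f"b{i}") for i in range(3)]
    result = ap.demultiplex_barcode_file(
        iter(barcode_reads), iter(bio_reads), meta, "same"
    )
    assert [r.read_id for r in result.assignments["s1"]] == ["b0"]
    assert [r.read_id for r in result.assignments["s2"]] == ["b1"]
    assert result.n_unassigned == 1
    # biological reads are not trimmed
    assert result.assignments["s1"][0].bases == "AAAA"


def test_demultiplex_barcode_file_unequal_counts():
    meta = ap.SampleMetadata({"s1": "ACGTA"})
    with pytest.raises(ValueError, match="different.*record counts"):
        ap.demultiplex_barcode_file(
            iter([make_read("ACGTA")]), iter([]), meta, "same"
        )


def test_resolve_orientation_raises_with_counts():
    result = ap.OrientationResult(5, 4, "ambiguous", 10.0, 9)
    with pytest.raises(AmbiguousOrientationError, match="5 reads.*4 match"):
        ap.resolve_orientation(result)
    assert ap.resolve_orientation(ap.OrientationResult(11, 1, "same")) == "same"
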