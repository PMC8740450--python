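"""Exception hierarchy for ampliprep.

Every failure mode that aborts a pipeline stage has its own exception type so
that the CLI can name the stage and exit non-zero with a useful diagnostic.
"""


class AmpliprepError(Exception):
    """Base class for all ampliprep errors."""


class ParseError(AmpliprepError):
    """A file did not conform to its expected format."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class MetadataError(AmpliprepError):
    """Sample metadata violated an invariant (duplicate ids, uneven barcodes...)."""


class AmbiguousOrientationError(AmpliprepError):
    """Neither barcode orientation dominated the other by the required ratio."""

    def __init__(self, n_same: int, n_revcomp: int, ratio: float):
        self.n_same = n_same
        self.n_revcomp = n_revcomp
        self.ratio = ratio
        super().__init__(
            f"barcode orientation is ambiguous: {n_same} reads match as-written, "
            f"{n_revcomp} match reverse-complemented; neither exceeds the other "
            f"by more than {ratio}x"
        )


class NoRegionError(AmpliprepError):
    """No contiguous high-quality run satisfied the cutoff and span requirements."""

    def __init__(self, message: str, best_run=None):
        self.best_run = best_run
        super().__init__(message)


class DepthError(AmpliprepError):
    """Rarefaction-depth selection or rarefaction itself is impossible."""


class MergeError(AmpliprepError):
    """Feature tables cannot be merged (overlapping samples, conflicting ids)."""
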