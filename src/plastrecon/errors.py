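"""Exception hierarchy for the package."""


class PlastreconError(Exception):
    """Base class for package errors."""


class ConfigError(PlastreconError):
    """Invalid simulation or pipeline configuration."""


class FastaParseError(PlastreconError):
    """Malformed FASTA input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NoQuadripartiteStructureError(PlastreconError):
    """No inverted-repeat pair of the required length was found."""


class NoPlastomeContigsError(PlastreconError):
    """Contig filtering retained nothing."""


class AnchorError(PlastreconError):
    """No seed-anchor chain between contig and reference."""


class CoverageError(PlastreconError):
    """Consensus requested over reference positions covered by no contig."""

    def __init__(self, gaps: list[tuple[int, int]]):
        self.gaps = gaps
        spans = ", ".join(f"[{s}, {e})" for s, e in gaps[:5])
        more = "" if len(gaps) <= 5 else f" and {len(gaps) - 5} more"
        super().__init__(f"uncovered reference interval(s): {spans}{more}")


class BandExceededError(PlastreconError):
    """Alignment band too narrow for the optimal path."""

    def __init__(self, band: int):
        self.band = band
        self.suggested = band * 2
        super().__init__(
            f"alignment exceeds band of {band}; retry with band >= {self.suggested}"
        )
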