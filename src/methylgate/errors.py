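"""Exception hierarchy shared across the package."""

from __future__ import annotations


class MethylgateError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MethylgateError, ValueError):
    """A value violates a documented precondition or invariant."""


class PlateFormatError(MethylgateError):
    """A plate file does not conform to the expected dialect."""


class DuplicateReactionError(PlateFormatError):
    """Two wells share the same (sample, gene, replicate) key."""

    def __init__(self, key: tuple) -> None:
        self.key = key
        super().__init__(f"duplicate reaction for (sample, gene, replicate) = {key!r}")


class NoReliableLimitError(MethylgateError):
    """No template amount in the array satisfies the full-detection criterion.

    Carries the offending (net_ng, detection) conditions so callers can
    report which cells broke the criterion.
    """

    def __init__(self, gene: str, offending: list) -> None:
        self.gene = gene
        self.offending = offending
        super().__init__(
            f"no reliable detection limit for {gene}: even the largest template "
            f"amount has incomplete detection in {len(offending)} condition(s)"
        )


class IncompleteReassayError(MethylgateError):
    """Re-assay records do not cover every sample that needed re-analysis."""

    def __init__(self, missing: list[str]) -> None:
        self.missing = sorted(missing)
        super().__init__(
            "re-assay is missing records for non-informative sample(s): "
            + ", ".join(self.missing)
        )


class UndefinedRateError(MethylgateError, ZeroDivisionError):
    """A positive rate was requested for an empty set of calls."""


class ZeroExpectedCountError(MethylgateError):
    """A contingency table has a zero expected count; the chi-square
    approximation is invalid and an exact test should be used instead."""
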