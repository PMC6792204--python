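"""Exception hierarchy shared across the package."""


class UtilmapError(Exception):
    """Base class for all package-specific errors."""


class ScoringError(UtilmapError):
    """FACT-B scoring failed (e.g. too many missing items in a subscale)."""


class ValueSetError(UtilmapError):
    """A value-set table does not cover the queried profile or is malformed."""


class RegistryError(UtilmapError, KeyError):
    """Unknown published model identifier."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class SpecificationError(UtilmapError):
    """A model term references an unknown variable or is ill-formed."""


class EstimationError(UtilmapError):
    """Model fitting failed (rank deficiency, separation, non-identifiability)."""


class LadderAbortError(EstimationError):
    """The specification ladder cannot proceed (no domain survived screening)."""


class EvaluationError(UtilmapError):
    """A goodness-of-fit metric is undefined for the given inputs."""
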