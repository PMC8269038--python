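"""Exception hierarchy for the SCP assay pipeline."""


class SCPAssayError(Exception):
    """Base class for all package errors."""


class ParameterError(SCPAssayError, ValueError):
    """Invalid or non-finite model/simulation parameters."""


class ValidationError(SCPAssayError, ValueError):
    """A domain object violates its invariants."""


class SchemaError(SCPAssayError, ValueError):
    """An input table does not conform to the expected schema."""


class GenerationError(SCPAssayError, RuntimeError):
    """Synthetic-experiment generation produced inconsistent output."""


class AnalysisError(SCPAssayError, RuntimeError):
    """An analysis step cannot be carried out on the given data."""


class DegenerateDataError(AnalysisError):
    """Data carry no information for the requested fit (e.g. all arms fully
    controlled or fully relapsed)."""


class FitError(AnalysisError):
    """A model fit failed or a required fit product is missing."""
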