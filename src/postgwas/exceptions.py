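"""Exception hierarchy shared by all pipeline stages.

``ParameterError``/``ValidationError``/``SchemaError`` signal bad user input
(CLI exit code 1); everything else derived from :class:`PostGwasError` is a
runtime failure (exit code 2).
"""


class PostGwasError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(PostGwasError, ValueError):
    """A configuration or scenario parameter is outside its documented range."""


class ValidationError(PostGwasError, ValueError):
    """An input table violates its schema-level contract (bad p-value,
    unknown category, conflicting annotation, ...)."""


class SchemaError(ValidationError):
    """A file is missing mandatory columns or cannot be parsed."""


class ConsistencyError(PostGwasError):
    """Cross-table referential integrity is broken (e.g. a causal SNP that
    is absent from the genotype panel)."""


class MissingVariantError(PostGwasError, KeyError):
    """A requested variant id is not present in the genotype panel."""


class MonomorphicVariantError(PostGwasError):
    """LD is undefined because a variant has zero dosage variance."""


class SamplingError(PostGwasError):
    """A resampling scheme cannot draw the requested number of genes."""


class DegenerateTestError(PostGwasError):
    """A statistical test cannot be computed (e.g. zero trial variance)."""


class StageError(PostGwasError):
    """A pipeline stage failed; carries the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        text = f"stage '{stage}' failed: {message}"
        if hint:
            text += f" (hint: {hint})"
        super().__init__(text)
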