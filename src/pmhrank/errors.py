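"""Exception hierarchy for pmhrank."""


class PmhRankError(Exception):
    """Base class for all pmhrank errors."""


class ConfigurationError(PmhRankError):
    """A questionnaire or catalogue configuration is invalid."""


class ValidationError(PmhRankError):
    """Input data violates a schema or range constraint."""


class ParameterError(PmhRankError):
    """A method parameter is outside its admissible range."""
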