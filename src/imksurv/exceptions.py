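"""Exception hierarchy for imksurv."""


class ImksurvError(Exception):
    """Base class for all imksurv errors."""


class InvalidContextError(ImksurvError, ValueError):
    """A microdosimetric context field is non-positive or otherwise unusable."""


class InvalidProtocolError(ImksurvError, ValueError):
    """An irradiation protocol is malformed (overlapping or unordered fractions)."""


class EstimationError(ImksurvError, RuntimeError):
    """A recovery-curve fit cannot be performed or is degenerate."""


class SamplerError(ImksurvError, RuntimeError):
    """The Metropolis sampler failed (e.g. chain stuck at near-zero acceptance)."""


class FormatError(ImksurvError, ValueError):
    """An input file does not match the documented schema."""
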