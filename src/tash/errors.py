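"""Exception hierarchy shared across the toolbox."""


class TashError(Exception):
    """Base class for all toolbox errors."""


class FormatError(TashError):
    """A file does not conform to the expected on-disk format."""


class ConsistencyError(TashError):
    """Internally inconsistent data (length/count mismatches, duplicates)."""


class ParameterError(TashError, ValueError):
    """An invalid parameter value was supplied."""


class ConfigurationError(TashError):
    """The pipeline configuration cannot be applied to the given inputs."""


class PipelineError(TashError):
    """A pipeline stage could not produce a result (e.g. no crown found)."""
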