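"""Exception hierarchy for the pipeline.

Every anticipated failure mode raises a subclass of :class:`ChimeraDeconvError`
so that the CLI can distinguish pipeline errors (exit status 1, stage named)
from genuine bugs.
"""


class ChimeraDeconvError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(ChimeraDeconvError):
    """Invalid parameters, missing samples, or inconsistent inputs."""


class VcfParseError(ChimeraDeconvError):
    """A VCF or BED record could not be interpreted."""


class EstimationError(ChimeraDeconvError):
    """An estimator was asked to run on data that cannot support it
    (e.g. zero informative sites or reads)."""
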