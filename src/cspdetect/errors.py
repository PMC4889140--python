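"""Exception hierarchy.

Detection failures are recoverable at the dataset level: ``analyze_trial``
converts them into flagged results rather than letting them propagate.
"""


class CSPDetectError(Exception):
    """Base class for all package errors."""


class ParameterError(CSPDetectError, ValueError):
    """Invalid configuration or generation parameter."""


class DetectionError(CSPDetectError, RuntimeError):
    """A detection stage could not produce a result.

    Parameters
    ----------
    message : str
    stage : str, optional
        Pipeline stage that failed (e.g. ``"csp_offset"``); recorded in the
        per-trial notes so flagged trials can be triaged offline.
    """

    def __init__(self, message: str, stage: str = ""):
        super().__init__(message)
        self.stage = stage


class TemplateMatchError(DetectionError):
    """The matched filter found no event above the similarity threshold."""


class MethodError(DetectionError):
    """A method-specific requirement was not met (e.g. too few peaks)."""
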