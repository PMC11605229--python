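"""Exception hierarchy.

``ValidationError`` marks bad user input (malformed files, inconsistent
configuration); the CLI maps it to exit code 2.  Everything else that the
package raises deliberately derives from ``ProxidiffError`` and maps to
exit code 1.
"""


class ProxidiffError(Exception):
    """Base class for errors raised by proxidiff."""


class ValidationError(ProxidiffError):
    """Invalid input data or configuration."""


class PipelineError(ProxidiffError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
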