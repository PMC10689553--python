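"""Exception types shared across the package."""


class MltscanError(Exception):
    """Base class for all package-specific errors."""


class DegenerateResponseError(MltscanError):
    """A metabolite cannot be encoded or fitted (all censored, constant, LOQ above data)."""

    def __init__(self, name: str, reason: str):
        self.name = name
        self.reason = reason
        super().__init__(f"degenerate response {name!r}: {reason}")


class SupportError(MltscanError):
    """Evaluation outside the bounded support of a Bernstein basis."""


class AlignmentError(MltscanError):
    """Rows of a response and a covariate matrix do not line up."""


class NotConvergedError(MltscanError):
    """An operation that needs a converged fit received a flagged one."""
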