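"""Exception hierarchy for the coilglobule package."""


class CoilGlobuleError(Exception):
    """Base class for all package errors."""


class UnsupportedModelError(CoilGlobuleError):
    """Requested water model is not one of the built-in parameter sets."""


class GeometryError(CoilGlobuleError):
    """Degenerate or inconsistent molecular geometry."""


class ParseError(CoilGlobuleError):
    """Malformed structure/trajectory file."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class TopologyError(CoilGlobuleError):
    """Topology annotation is inconsistent with the requested analysis."""


class EmptySelectionError(CoilGlobuleError):
    """An atom selection required by an observable is empty."""


class EmptyShellError(CoilGlobuleError):
    """Hydration statistic undefined because the relevant water set is empty."""


class NoTransitionError(CoilGlobuleError):
    """Sigmoid fit failed to converge or the series carries no transition."""


class ChainBuildError(CoilGlobuleError):
    """Self-avoiding chain placement failed after bounded retries."""


class SolvationError(CoilGlobuleError):
    """Requested solvent density or geometry cannot be realised."""


class PipelineError(CoilGlobuleError):
    """A pipeline stage failed; carries the stage and state-point labels."""

    def __init__(self, stage: str, state_point=None, cause: Exception | None = None):
        msg = f"stage '{stage}' failed"
        if state_point is not None:
            msg += f" at state point {state_point}"
        if cause is not None:
            msg += f": {cause}"
        super().__init__(msg)
        self.stage = stage
        self.state_point = state_point
        self.cause = cause
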