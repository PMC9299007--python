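"""Exception hierarchy shared across the pipeline stages."""


class SocPotentialError(Exception):
    """Base class for all package-specific errors."""


class NoDataError(SocPotentialError):
    """An operation received an empty table or zero total area."""


class ImputationUnavailableError(SocPotentialError):
    """No reported-variation records exist in the group needed for CV imputation."""


class NoEffectError(SocPotentialError):
    """An (intervention, climate) cell has no pooled effect and no fallback."""


class AlignmentError(SocPotentialError):
    """Keys of two tables that must join exactly do not align."""


class ConfigError(SocPotentialError):
    """A generator or pipeline configuration is infeasible or inconsistent."""


class StageError(SocPotentialError):
    """A pipeline stage failed; carries the stage name for atomic reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
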