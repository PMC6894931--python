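"""Exception hierarchy shared across the package."""


class MultipatchError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(MultipatchError, ValueError):
    """An argument violates a documented precondition."""


class InvalidPlanError(MultipatchError, ValueError):
    """A session plan violates its invariants."""


class DegenerateGeometryError(MultipatchError, ValueError):
    """Point sets are collinear/degenerate and cannot define a rigid transform."""


class InvalidPoseError(MultipatchError, ValueError):
    """Pipette poses are inconsistent (e.g. duplicate azimuths)."""


class PathInfeasibleError(MultipatchError, ValueError):
    """No axis-aligned approach path exists from the given pose."""


class ProtocolViolationError(MultipatchError, RuntimeError):
    """An illegal patching-phase transition or forbidden rig action."""


class InvalidKineticsError(MultipatchError, ValueError):
    """PSP kinetics with rise >= decay are not a valid double exponential."""


class FeatureUndefinedError(MultipatchError, ValueError):
    """A waveform feature (e.g. AP threshold) could not be determined."""


class StimulusNotFoundError(MultipatchError, ValueError):
    """No stimulus in the scanned grid elicited an action potential."""


class CoverageMismatchError(MultipatchError, ValueError):
    """Connection calls do not cover exactly the pairs mandated by the plan."""

    def __init__(self, missing=(), extra=()):
        self.missing = sorted(missing)
        self.extra = sorted(extra)
        super().__init__(
            f"call coverage mismatch: missing pairs {self.missing}, "
            f"unexpected pairs {self.extra}"
        )


class UnsupportedVersionError(MultipatchError, ValueError):
    """Recording-container manifest version is not supported."""


class IntegrityError(MultipatchError, ValueError):
    """Recording container is structurally corrupt."""


class ConfigError(MultipatchError, ValueError):
    """Pipeline configuration is schema-invalid."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid config: " + "; ".join(self.problems))
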