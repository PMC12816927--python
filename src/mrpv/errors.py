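"""Exception types shared across the package."""


class MRPVError(Exception):
    """Base class for all package-specific errors."""


class ZeroCellError(MRPVError):
    """A 2x2 contingency table has an empty cell and no continuity correction
    was requested, so the reporting odds ratio is undefined."""


class UnknownTermError(MRPVError):
    """A preferred term is missing from the coding hierarchy."""


class InstrumentSelectionError(MRPVError):
    """No variant survived instrument selection.

    Carries the per-stage survivor counts so callers can see which filter
    emptied the set.
    """

    def __init__(self, message: str, stage_counts: dict | None = None):
        super().__init__(message)
        self.stage_counts = dict(stage_counts or {})

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        base = super().__str__()
        if self.stage_counts:
            trail = " -> ".join(f"{k}={v}" for k, v in self.stage_counts.items())
            return f"{base} [{trail}]"
        return base


class ConfigError(MRPVError):
    """Invalid or incomplete run configuration."""
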