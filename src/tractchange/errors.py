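"""Exception hierarchy shared across the package."""


class TractChangeError(Exception):
    """Base class for all package-specific errors."""


class PanelValidationError(TractChangeError):
    """A tract panel (or one of its cells) violates an invariant."""


class MissingDataError(TractChangeError):
    """A required observation or variable is absent."""


class ConfigError(TractChangeError):
    """A classifier or run configuration is unsatisfiable for the given panel."""
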