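"""Typed exceptions shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid task, agent or cell-population configuration."""


class ValidationError(ValueError):
    """A data table violates a structural invariant (names the row/column)."""


class BoundsError(ValueError):
    """A requested window falls outside the recorded trace."""


class SessionNotDecodableError(ValueError):
    """A side x outcome condition is empty, so balanced training is impossible."""


class NotComputableError(ValueError):
    """A behavioral index is undefined for this session (e.g. no losses)."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank deficient after dropping constant columns."""
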