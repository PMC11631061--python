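"""Exception hierarchy for atriapace."""


class AtriapaceError(Exception):
    """Base class for all package errors."""


class ParameterError(AtriapaceError):
    """A model or algorithm parameter violates its constraints."""


class StateError(AtriapaceError):
    """A model state is physically inadmissible (e.g. negative volume)."""


class IntegrationError(AtriapaceError):
    """The ODE integration failed; carries diagnostics in args."""


class RegulationError(AtriapaceError):
    """Pressure-flow regulation diverged; carries the last good state."""


class DataError(AtriapaceError):
    """A recording or table is missing required channels/columns."""


class InsufficientDataError(DataError):
    """Input too short or too small for the requested analysis."""


class ConfigError(AtriapaceError):
    """A run/synthesis configuration is invalid."""


class ExtrapolationError(AtriapaceError):
    """A requested point lies outside the computed grid."""
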