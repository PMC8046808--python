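"""Exception hierarchy shared across the package."""


class DendrionError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DendrionError, ValueError):
    """A parameter is outside its admissible range."""


class InitializationError(DendrionError):
    """Particle placement failed (box too small, retry budget exhausted)."""


class OverstretchError(DendrionError):
    """A FENE bond reached or exceeded its maximum extension R0."""


class SimulationFault(DendrionError):
    """The integrator produced a non-finite or overstretched state.

    Carries the step index at which the fault occurred and, when raised by
    :func:`dendrion.simulator.run_simulation`, the last good frame.
    """

    def __init__(self, message, step=None, last_good_frame=None):
        super().__init__(message)
        self.step = step
        self.last_good_frame = last_good_frame


class UnwrapError(DendrionError):
    """Bonded coordinates could not be unwrapped across periodic images."""


class InsufficientStatisticsError(DendrionError):
    """Trajectory too short for the requested block-averaged estimate."""


class ConfigError(DendrionError, ValueError):
    """Run-configuration validation failed; message lists all violations."""


class TrajectoryParseError(DendrionError):
    """A trajectory file is malformed; message names the line/frame."""
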