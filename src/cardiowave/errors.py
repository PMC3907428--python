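"""Exception hierarchy for cardiowave."""


class CardiowaveError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CardiowaveError, ValueError):
    """A scalar/array input violates an operation precondition."""


class InvalidStateError(CardiowaveError, ValueError):
    """A membrane/tissue state violates its invariants (e.g. Cai <= 0)."""


class DegenerateRatesError(CardiowaveError, ValueError):
    """alpha + beta == 0: the gate steady state is undefined."""


class NoRestStateError(CardiowaveError, RuntimeError):
    """The total-current root finder found no sign change on its bracket."""


class NumericalInstabilityError(CardiowaveError, RuntimeError):
    """Vm left its sanity bounds during integration.

    Carries the step index, the offending node (ix, iy) and, when raised from
    a tissue run, the last valid Vm snapshot for post-mortem inspection.
    """

    def __init__(self, message, step=None, node=None, last_snapshot=None):
        super().__init__(message)
        self.step = step
        self.node = node
        self.last_snapshot = last_snapshot


class ConfigError(CardiowaveError, ValueError):
    """Configuration file parse error or invariant violation."""


class SnapshotFormatError(CardiowaveError, ValueError):
    """Snapshot file has a bad magic string, version, or truncated payload."""


class NoActionPotentialError(CardiowaveError, ValueError):
    """A probe trace contains no identifiable action potential upstroke."""


class NotActivatedError(CardiowaveError, ValueError):
    """An activation-map query touched a never-activated (sentinel) node."""
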