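"""Exception hierarchy shared across the package.

Every error the library raises deliberately derives from :class:`EigSearchError`,
so callers (and the CLI) can map failure categories to exit codes without
string-matching messages.
"""


class EigSearchError(Exception):
    """Base class for all deliberate errors raised by this package."""


class GraphInvariantError(EigSearchError, ValueError):
    """A graph or explanation violates a structural invariant."""


class UnknownTechniqueError(EigSearchError, ValueError):
    """Subgraph-inducing technique not one of node / edge / node_and_edge."""


class EmptyExplanationError(EigSearchError, ValueError):
    """A metric was requested on an empty explanation (undefined, e.g. 0/0)."""


class SizeGuardError(EigSearchError, ValueError):
    """Exhaustive enumeration requested on a graph too large to enumerate."""


class CapabilityError(EigSearchError, RuntimeError):
    """Predictor lacks a capability (e.g. gradients) the operation needs."""


class ContractError(EigSearchError, ValueError):
    """Predictor output violates the contract (shape, simplex, finiteness)."""


class ZeroDistanceError(EigSearchError, ValueError):
    """Baseline adjacency coincides with the input; the slope is undefined."""


class SchemaError(EigSearchError, ValueError):
    """Malformed or inconsistent serialized input."""
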