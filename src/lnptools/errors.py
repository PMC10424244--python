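"""Exception hierarchy shared across the toolkit."""


class LnpError(Exception):
    """Base class for all toolkit errors."""


class ParseError(LnpError):
    """A structure or trajectory file could not be parsed."""


class TopologyError(LnpError):
    """Bonds or molecule grouping are inconsistent with the atom table."""


class ShapeError(LnpError):
    """A trajectory frame does not match its topology."""


class GeometryError(LnpError):
    """A geometric precondition failed (missing reference atoms, degenerate axis...)."""


class SelectionError(LnpError):
    """A named-atom or predicate selection matched nothing it required."""


class CompositionError(LnpError):
    """A requested lipid composition is infeasible."""


class PlacementError(LnpError):
    """Template placement failed to align within tolerance."""


class RepairError(LnpError):
    """Ring-piercing repair did not converge."""


class FixtureError(LnpError):
    """A synthetic-fixture specification cannot be realized."""


class NumericalError(LnpError):
    """A numerical routine produced non-finite values."""
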