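"""Exception hierarchy for mtmixgraph."""


class MtMixError(Exception):
    """Base class for all mtmixgraph errors."""


class VariantParseError(MtMixError, ValueError):
    """A variant token or string could not be parsed."""


class PositionBoundsError(MtMixError, ValueError):
    """A variant position falls outside the reference sequence."""


class ProfileConsistencyError(MtMixError, ValueError):
    """A set of variant calls is internally inconsistent (e.g. partially
    overlapping indels, conflicting insertions at one anchor)."""


class GraphConstructionError(MtMixError, ValueError):
    """A variation-graph construction step was applied twice to the same
    position or conflicts with an earlier step."""


class SimulationError(MtMixError, RuntimeError):
    """The mixture simulator could not satisfy its sampling constraints."""
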