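"""Exception types shared across the analysis stages."""


class FlockscaleError(Exception):
    """Base class for package-specific failures."""


class TrackFormatError(FlockscaleError, ValueError):
    """A track table cannot be parsed (missing or unresolvable columns)."""


class TrackValidationError(FlockscaleError, ValueError):
    """A parsed track table violates an invariant (duplicates, order)."""


class NoCrossingError(FlockscaleError, RuntimeError):
    """C(r) never crosses zero on the evaluated grid."""


class DisconnectedGraphError(FlockscaleError, ValueError):
    """The neighborhood graph has more than one connected component."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"neighborhood graph has {n_components} connected components; "
            "the spin-wave partition function requires a connected graph"
        )


class DivergenceError(FlockscaleError, ValueError):
    """A perfectly ordered snapshot (C_int = 1) makes J unidentifiable."""


class FitFailureError(FlockscaleError, RuntimeError):
    """A likelihood profile contained no finite values."""
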