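"""Exception hierarchy shared across polypat modules."""


class PolypatError(Exception):
    """Base class for all polypat errors."""


class PanelError(PolypatError, ValueError):
    """Malformed or inconsistent genotype panel."""


class InfeasibleMarkerSet(PanelError):
    """No marker subset can satisfy the requested distinguishing property."""


class ConfigurationError(PolypatError, ValueError):
    """Invalid run or simulation configuration."""


class DataError(PolypatError, ValueError):
    """Inconsistent data passed between pipeline stages."""
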